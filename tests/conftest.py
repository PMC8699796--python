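import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pdxdrift import SnpMarker, SnpPanel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_panel(n: int = 20, maf: float | None = None, seed: int = 0) -> SnpPanel:
    """Deterministic little panel; per-marker MAF fixed or drawn U[0.40, 0.50]."""
    rng = np.random.default_rng(seed)
    mafs = np.full(n, maf) if maf is not None else rng.uniform(0.40, 0.50, n)
    markers = [
        SnpMarker(
            marker_id=f"rs{i:04d}",
            chromosome="1",
            position=1000 * (i + 1),
            allele_a="A",
            allele_b="G",
            maf=float(mafs[i]),
        )
        for i in range(n)
    ]
    return SnpPanel(markers)


@pytest.fixture
def panel20() -> SnpPanel:
    return make_panel(20)


@pytest.fixture
def panel300() -> SnpPanel:
    return make_panel(300, seed=1)
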