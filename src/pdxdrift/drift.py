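"""Pairwise SNP concordance and passage-drift statistics.

Concordance between two samples is the fraction of panel markers, called in
*both* samples, at which the genotype states are identical; the alteration
rate (1 - concordance) is the working measure of genetic drift between a
patient tumor and its xenograft passages. Comparison is pairwise-complete:
markers missing in either sample are excluded and the number actually
compared is always reported, so low-call-rate samples stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeVector
from .markers import SnpPanel
from .simulate import PdxLineage, StabilityClass

DEFAULT_STABILITY_THRESHOLD = 0.95


class UndefinedComparisonError(ValueError):
    """Raised when two samples share no called markers (nCompared = 0)."""


class MissingSampleError(KeyError):
    """Raised when a lineage sample is absent from the genotype collection."""


@dataclass(frozen=True)
class ConcordanceResult:
    """Outcome of one pairwise genotype comparison."""

    sample_a: str
    sample_b: str
    n_compared: int
    n_matching: int

    @property
    def concordance(self) -> float:
        return self.n_matching / self.n_compared

    @property
    def alteration_rate(self) -> float:
        return 1.0 - self.concordance


def concordance(
    a: GenotypeVector, b: GenotypeVector, panel: SnpPanel | None = None
) -> ConcordanceResult:
    """Compare two aligned genotype vectors over their co-called markers.

    Raises
    ------
    UndefinedComparisonError
        If no marker is called in both samples — deliberately distinct
        from a concordance of zero.
    """
    if len(a) != len(b):
        raise ValueError(
            f"vectors {a.sample_id!r} ({len(a)}) and {b.sample_id!r} "
            f"({len(b)}) are not aligned"
        )
    if panel is not None and len(a) != panel.size:
        raise ValueError(
            f"vectors of length {len(a)} not aligned to panel of size {panel.size}"
        )
    both = (a.calls != MISSING) & (b.calls != MISSING)
    n_compared = int(both.sum())
    if n_compared == 0:
        raise UndefinedComparisonError(
            f"no co-called markers between {a.sample_id!r} and {b.sample_id!r}"
        )
    n_matching = int((a.calls[both] == b.calls[both]).sum())
    return ConcordanceResult(a.sample_id, b.sample_id, n_compared, n_matching)


@dataclass(frozen=True)
class DriftTrajectory:
    """Alteration-rate trajectories of one lineage.

    ``cumulative[p]`` compares passage p against the patient tumor;
    ``incremental[p]`` compares passage p against passage p-1 (for p = 1
    the two coincide). Both views are kept because either comparison is a
    legitimate reading of a per-passage drift profile.
    """

    lineage_id: str
    cumulative: dict[int, float]
    incremental: dict[int, float]


def drift_trajectory(
    lineage: PdxLineage,
    genotypes: Mapping[str, GenotypeVector],
    panel: SnpPanel | None = None,
) -> DriftTrajectory:
    """Alteration rates of every passage vs the PT and vs the prior passage."""

    def get(sample_id: str, passage: str) -> GenotypeVector:
        try:
            return genotypes[sample_id]
        except KeyError:
            raise MissingSampleError(
                f"lineage {lineage.lineage_id}: sample {sample_id!r} "
                f"({passage}) absent from genotype collection"
            ) from None

    pt = get(lineage.patient_sample_id, "PT")
    cumulative: dict[int, float] = {}
    incremental: dict[int, float] = {}
    prev = pt
    for p in range(1, lineage.n_passages + 1):
        sample = get(lineage.passage_sample_id(p), f"P{p}")
        cumulative[p] = concordance(pt, sample, panel).alteration_rate
        incremental[p] = concordance(prev, sample, panel).alteration_rate
        prev = sample
    return DriftTrajectory(lineage.lineage_id, cumulative, incremental)


def cohort_drift_summary(
    trajectories: Iterable[DriftTrajectory], which: str = "cumulative"
) -> pd.DataFrame:
    """Pool alteration rates across lineages: per-passage mean and SEM.

    SEM uses the sample standard deviation (ddof=1); a passage contributed
    by a single lineage gets SEM 0.0 with ``single_lineage`` flagged True.
    """
    if which not in ("cumulative", "incremental"):
        raise ValueError(f"which must be 'cumulative' or 'incremental', got {which!r}")
    pooled: dict[int, list[float]] = {}
    for t in trajectories:
        for p, rate in getattr(t, which).items():
            pooled.setdefault(p, []).append(rate)
    rows = []
    for p in sorted(pooled):
        vals = np.asarray(pooled[p], dtype=float)
        n = vals.size
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "passage": p,
                "mean": float(vals.mean()),
                "sem": sem,
                "n_lineages": n,
                "single_lineage": n == 1,
            }
        )
    return pd.DataFrame(
        rows, columns=["passage", "mean", "sem", "n_lineages", "single_lineage"]
    )


def classify_stability(
    lineage: PdxLineage,
    genotypes: Mapping[str, GenotypeVector],
    panel: SnpPanel | None = None,
    threshold: float = DEFAULT_STABILITY_THRESHOLD,
) -> StabilityClass:
    """Call a lineage UNSTABLE iff PT-vs-P1 concordance falls below threshold.

    The default 0.95 sits midway between the reported stable (98.2%) and
    unstable (90.0%) class means; the comparison is inclusive, so a
    concordance exactly at threshold is STABLE.
    """
    if lineage.n_passages < 1:
        raise MissingSampleError(f"lineage {lineage.lineage_id} has no P1")
    try:
        pt = genotypes[lineage.patient_sample_id]
        p1 = genotypes[lineage.passage_sample_id(1)]
    except KeyError as e:
        raise MissingSampleError(
            f"lineage {lineage.lineage_id}: sample {e.args[0]!r} absent"
        ) from None
    c = concordance(pt, p1, panel).concordance
    return StabilityClass.STABLE if c >= threshold else StabilityClass.UNSTABLE
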