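"""Small-sample clinical statistics around the engraftment cohort.

Covers the exact 2x2 engraftment tests, take-rate summaries, the caliper
tumor-volume formula V = L * W^2 / 2, platinum-response categorisation
(PFS >= 6 months = sensitive), and the treated-to-control (T/C) volume
ratio used to score in vivo drug response.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class PlatinumResponse(enum.Enum):
    SENSITIVE = "SENSITIVE"
    RESISTANT = "RESISTANT"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = engrafted/failed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("all-zero contingency table")

    @property
    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_2x2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p-value for a 2x2 table.

    Uses the standard two-sided convention: the sum over all tables with
    the observed margins whose hypergeometric point probability does not
    exceed the observed table's (ties resolved with a ~1e-7 relative
    tolerance). A table with a zero margin has p = 1.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    return float(stats.fisher_exact(table.as_array, alternative="two-sided")[1])


def engraftment_rate(n_engrafted: int, n_total: int) -> int:
    """Take rate as the integer percentage a results table prints."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_engrafted <= n_total:
        raise ValueError(f"n_engrafted {n_engrafted} outside 0..{n_total}")
    return int(np.floor(100.0 * n_engrafted / n_total + 0.5))


def engraftment_summary(
    strata: Mapping[str, ContingencyTable2x2],
    overall: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Take rates and Fisher p-values per stratum.

    Each stratum is a 2x2 of (engrafted, failed) counts for its two
    groups; rates are reported as integer percentages as printed in a
    cohort table, with the two-sided Fisher p for the group contrast.
    """
    if not strata and overall is None:
        raise ValueError("empty cohort: no strata and no overall counts")
    rows = []
    if overall is not None:
        n_eng, n_tot = overall
        rows.append(
            {
                "stratum": "overall",
                "rate_group1_pct": engraftment_rate(n_eng, n_tot),
                "rate_group2_pct": np.nan,
                "p_value": np.nan,
            }
        )
    for name, t in strata.items():
        rows.append(
            {
                "stratum": name,
                "rate_group1_pct": engraftment_rate(t.a, t.a + t.b),
                "rate_group2_pct": engraftment_rate(t.c, t.c + t.d),
                "p_value": fisher_exact_2x2(t),
            }
        )
    return pd.DataFrame(
        rows, columns=["stratum", "rate_group1_pct", "rate_group2_pct", "p_value"]
    )


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume in mm^3: V = length * width^2 / 2.

    By convention ``length`` is the larger caliper axis; the formula is
    evaluated as given either way.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("caliper measurements must be non-negative")
    return 0.5 * length_mm * width_mm**2


def classify_platinum_response(pfs_months: float) -> PlatinumResponse:
    """SENSITIVE iff progression-free survival is at least six months."""
    if pfs_months < 0:
        raise ValueError("PFS cannot be negative")
    return (
        PlatinumResponse.SENSITIVE if pfs_months >= 6.0 else PlatinumResponse.RESISTANT
    )


@dataclass(frozen=True)
class TreatmentArm:
    """Tumor volumes (mm^3) of one arm at a fixed timepoint."""

    arm_label: str
    tumor_volumes: tuple[float, ...]

    def __init__(self, arm_label: str, tumor_volumes) -> None:
        vols = tuple(float(v) for v in tumor_volumes)
        if any(v < 0 for v in vols):
            raise ValueError("tumor volumes must be non-negative")
        object.__setattr__(self, "arm_label", arm_label)
        object.__setattr__(self, "tumor_volumes", vols)

    @property
    def mean_volume(self) -> float:
        if not self.tumor_volumes:
            raise ValueError(f"arm {self.arm_label!r} is empty")
        return float(np.mean(self.tumor_volumes))


def tc_ratio(treated: TreatmentArm, control: TreatmentArm) -> float:
    """Treated-to-control mean volume ratio, as a percentage."""
    control_mean = control.mean_volume
    if control_mean <= 0:
        raise ValueError("control arm mean volume must be positive")
    return 100.0 * treated.mean_volume / control_mean


# Printed engraftment cohort counts (rows: group with trait / without,
# columns: engrafted / failed; Fisher's p is transpose-invariant). The
# recurrence table is engrafted/failed x recurrence(<12/>12 months),
# reconstructed from the cohort table's own percentages and margins — its
# printed cells are internally inconsistent with its printed column totals.
TABLE1_RECURRENCE_LT12 = ContingencyTable2x2(24, 3, 5, 4)
TABLE1_MOUSE_STRAIN = ContingencyTable2x2(12, 5, 21, 5)
TABLE1_FRESH_FROZEN = ContingencyTable2x2(8, 2, 15, 8)
TABLE1_STAGE_IIIC = ContingencyTable2x2(27, 6, 6, 4)
TABLE1_OVERALL = (33, 43)
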