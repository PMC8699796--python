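"""Sample-pair authentication: matched, unrelated, or lymphoma-contaminated.

The three populations a xenograft bank encounters occupy well-separated
concordance regimes over a common-SNP signature: a passage matches its own
patient tumor at ~94% of markers, unrelated human samples agree at the
~39% chance level, and mouse-lymphoma takeover collapses both the human
call rate and the residual concordance (~21%). The verdict thresholds sit
in the empty margins between those regimes and are configurable.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field

import pandas as pd

from .drift import concordance
from .genotypes import GenotypeVector
from .markers import SnpPanel
from .simulate import Cohort


class Verdict(enum.Enum):
    MATCHED = "MATCHED"
    UNRELATED = "UNRELATED"
    CONTAMINATED = "CONTAMINATED"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class AuthenticationThresholds:
    """Decision boundaries for the authentication rule.

    matched_min : concordance at or above which a pair is MATCHED.
    contaminated_max : concordance below which a pair is CONTAMINATED.
    min_call_rate : call rate below which a sample is treated as
        contaminated regardless of concordance — mouse DNA on a human
        array primarily fails to genotype, so the call-rate gate fires
        before the concordance rule.
    min_compared : floor on co-called markers below which the concordance
        fraction is too noisy to act on (INDETERMINATE).
    """

    matched_min: float = 0.80
    contaminated_max: float = 0.30
    min_call_rate: float = 0.50
    min_compared: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.contaminated_max <= self.matched_min <= 1.0:
            raise ValueError(
                "need 0 <= contaminated_max <= matched_min <= 1, got "
                f"{self.contaminated_max} / {self.matched_min}"
            )


DEFAULT_THRESHOLDS = AuthenticationThresholds()


@dataclass(frozen=True)
class AuthenticationVerdict:
    verdict: Verdict
    sample_a: str
    sample_b: str
    concordance: float  # nan when indeterminate with no usable comparison
    call_rate_a: float
    call_rate_b: float
    n_compared: int
    thresholds: AuthenticationThresholds = field(
        default=DEFAULT_THRESHOLDS, compare=False
    )


def authenticate(
    a: GenotypeVector,
    b: GenotypeVector,
    panel: SnpPanel | None = None,
    thresholds: AuthenticationThresholds = DEFAULT_THRESHOLDS,
) -> AuthenticationVerdict:
    """Classify a sample pair from its concordance and call-rate profile.

    Rule order: call-rate gate (CONTAMINATED), comparison floor
    (INDETERMINATE), concordance below ``contaminated_max``
    (CONTAMINATED), at or above ``matched_min`` (MATCHED), else UNRELATED.
    Symmetric in (a, b).
    """
    cra, crb = a.call_rate, b.call_rate
    both = a.called_mask & b.called_mask
    n_compared = int(both.sum())
    conc = (
        concordance(a, b, panel).concordance if n_compared > 0 else math.nan
    )

    if cra < thresholds.min_call_rate or crb < thresholds.min_call_rate:
        verdict = Verdict.CONTAMINATED
    elif n_compared < thresholds.min_compared:
        verdict = Verdict.INDETERMINATE
    elif conc < thresholds.contaminated_max:
        verdict = Verdict.CONTAMINATED
    elif conc >= thresholds.matched_min:
        verdict = Verdict.MATCHED
    else:
        verdict = Verdict.UNRELATED
    return AuthenticationVerdict(
        verdict=verdict,
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        concordance=conc,
        call_rate_a=cra,
        call_rate_b=crb,
        n_compared=n_compared,
        thresholds=thresholds,
    )


@dataclass(frozen=True)
class QcReport:
    """Per-passage authentication of every lineage against its patient tumor."""

    rows: tuple[AuthenticationVerdict, ...]
    lineage_of: dict[tuple[str, str], str]

    def to_dataframe(self) -> pd.DataFrame:
        records = [
            {
                "lineage_id": self.lineage_of[(r.sample_a, r.sample_b)],
                "patient_sample": r.sample_a,
                "passage_sample": r.sample_b,
                "verdict": r.verdict.value,
                "concordance": r.concordance,
                "call_rate_pt": r.call_rate_a,
                "call_rate_passage": r.call_rate_b,
                "n_compared": r.n_compared,
                "flagged": r.verdict is not Verdict.MATCHED,
            }
            for r in self.rows
        ]
        return pd.DataFrame(
            records,
            columns=[
                "lineage_id",
                "patient_sample",
                "passage_sample",
                "verdict",
                "concordance",
                "call_rate_pt",
                "call_rate_passage",
                "n_compared",
                "flagged",
            ],
        )

    def to_json(self) -> str:
        return json.dumps(
            self.to_dataframe().to_dict(orient="records"), indent=2, allow_nan=True
        )

    def to_text(self) -> str:
        df = self.to_dataframe()
        if df.empty:
            return "QC report: no lineages.\n"
        n_flagged = int(df["flagged"].sum())
        lines = [
            f"QC report: {df['lineage_id'].nunique()} lineages, "
            f"{len(df)} passages authenticated, {n_flagged} flagged.",
            df.to_string(index=False, float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines) + "\n"

    @property
    def flagged(self) -> tuple[AuthenticationVerdict, ...]:
        return tuple(r for r in self.rows if r.verdict is not Verdict.MATCHED)


def qc_report(
    cohort: Cohort,
    thresholds: AuthenticationThresholds = DEFAULT_THRESHOLDS,
) -> QcReport:
    """Authenticate every passage of every lineage against its PT."""
    rows: list[AuthenticationVerdict] = []
    lineage_of: dict[tuple[str, str], str] = {}
    for lineage in cohort.lineages:
        pt = cohort.samples[lineage.patient_sample_id]
        for p in range(1, lineage.n_passages + 1):
            passage = cohort.samples[lineage.passage_sample_id(p)]
            v = authenticate(pt, passage, cohort.panel, thresholds)
            rows.append(v)
            lineage_of[(v.sample_a, v.sample_b)] = lineage.lineage_id
    return QcReport(rows=tuple(rows), lineage_of=lineage_of)
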