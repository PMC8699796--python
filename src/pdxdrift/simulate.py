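"""Synthetic PDX cohort generator.

Emulates the genotype data a serially-passaged xenograft study produces:
patient tumors (PT) drawn under Hardy-Weinberg proportions over a common-SNP
panel, serial passages (P1..Pn) that drift away from the patient genotype at
configurable per-passage rates, stromal (mouse cell) admixture degrading the
call rate, mouse-lymphoma takeover collapsing human-SNP concordance, and
near-identical duplicate samples.

Drift model
-----------
Each non-missing call is independently altered with probability ``d``; an
alteration always produces a *different* genotype state — a heterozygote
becomes either homozygote with equal probability (loss of heterozygosity,
the dominant mode in genomically unstable serous tumors) and a homozygote
becomes heterozygous. The expected fraction of altered compared calls
therefore equals ``d`` exactly, which is what the concordance pipeline is
meant to recover.

Seeding
-------
One master seed; every sample stream is a ``numpy.random.SeedSequence``
spawned with a documented ``spawn_key`` (see ``derive_rng``), so any single
sample can be regenerated without replaying the whole cohort.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict
from collections.abc import Mapping, Sequence

import numpy as np

from .genotypes import MISSING, GenotypeVector
from .markers import SnpMarker, SnpPanel
from .panel import select_panel

_ALLELE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]

# spawn-key namespaces for per-sample random streams
_NS_MARKERS = 0
_NS_PATIENT = 1
_NS_PASSAGE = 2
_NS_STROMA = 3
_NS_DUPLICATE = 4
_NS_CONTAMINATION = 5


class StabilityClass(enum.Enum):
    STABLE = "STABLE"
    UNSTABLE = "UNSTABLE"


class BrcaStatus(enum.Enum):
    MUTANT = "MUTANT"
    WILDTYPE = "WILDTYPE"
    UNKNOWN = "UNKNOWN"


class InvalidConfigError(ValueError):
    """Raised for an infeasible or out-of-range simulation configuration."""


@dataclass(frozen=True)
class PdxLineage:
    """A patient tumor and its ordered serial xenograft passages."""

    lineage_id: str
    patient_sample_id: str
    passage_sample_ids: tuple[str, ...]
    stability_class: StabilityClass
    brca_status: BrcaStatus = BrcaStatus.UNKNOWN
    contaminated_passages: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        n = len(self.passage_sample_ids)
        declared = set(range(1, n + 1))
        if not set(self.contaminated_passages) <= declared:
            raise ValueError(
                f"lineage {self.lineage_id}: contaminated passages "
                f"{sorted(self.contaminated_passages)} outside declared 1..{n}"
            )

    @property
    def n_passages(self) -> int:
        return len(self.passage_sample_ids)

    def passage_sample_id(self, passage: int) -> str:
        """Sample id of passage ``passage`` (1-based)."""
        if not 1 <= passage <= self.n_passages:
            raise KeyError(f"lineage {self.lineage_id} has no passage {passage}")
        return self.passage_sample_ids[passage - 1]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for a synthetic PDX cohort.

    Defaults encode the study conditions the pipeline is designed around:
    a 300-SNP signature at MAF >= 0.40 drawn from a quarter-million
    candidate exonic markers; 17 lineages of which 8 are "unstable"
    (initiation drift 10.0%, i.e. PT-vs-P1 concordance 90.0%) and 9
    "stable" (1.8%, concordance 98.2%); 0.6% drift per passage P2-P6 with
    a 3.7% uptick at P7; stromal fractions of 27-55% mouse cells mapped to
    extra missingness; and lymphoma contamination modeled as a collapsed
    call rate with ~21% residual concordance against the lineage's PT.
    """

    seed: int = 0
    n_candidate_markers: int = 250_000
    panel_size: int = 300
    maf_range: tuple[float, float] = (0.40, 0.50)
    n_lineages: int = 17
    n_unstable: int = 8
    max_passage: int = 7
    initiation_drift_stable: float = 0.018
    initiation_drift_unstable: float = 0.100
    per_passage_drift: float = 0.006
    late_passage_drift: float = 0.037
    assay_noise_rate: float = 0.0
    missing_rate_base: float = 0.01
    stromal_fraction_range: tuple[float, float] = (0.27, 0.55)
    stromal_missing_scale: float = 0.2
    contamination_call_rate: float = 0.40
    contamination_match_rate: float = 0.21
    n_duplicates: int = 0
    contaminated_passages: tuple[tuple[int, int], ...] = ()
    """Pairs (lineage index, passage number) replaced by lymphoma samples."""

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError(
                f"maf_range {self.maf_range} must be a non-empty interval within (0, 0.5]"
            )
        if self.panel_size > self.n_candidate_markers:
            raise InvalidConfigError(
                f"panel_size {self.panel_size} exceeds "
                f"n_candidate_markers {self.n_candidate_markers}"
            )
        if self.n_unstable > self.n_lineages:
            raise InvalidConfigError(
                f"n_unstable {self.n_unstable} exceeds n_lineages {self.n_lineages}"
            )
        if self.n_duplicates > self.n_lineages:
            raise InvalidConfigError("n_duplicates exceeds n_lineages")
        for name in (
            "initiation_drift_stable",
            "initiation_drift_unstable",
            "per_passage_drift",
            "late_passage_drift",
            "assay_noise_rate",
            "missing_rate_base",
            "contamination_call_rate",
            "contamination_match_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} outside [0, 1]")
        slo, shi = self.stromal_fraction_range
        if not (0.0 <= slo <= shi <= 1.0):
            raise InvalidConfigError(
                f"stromal_fraction_range {self.stromal_fraction_range} outside [0, 1]"
            )
        if self.max_passage < 1 or self.n_lineages < 1:
            raise InvalidConfigError("max_passage and n_lineages must be >= 1")
        for li, p in self.contaminated_passages:
            if not 0 <= li < self.n_lineages:
                raise InvalidConfigError(f"contaminated lineage index {li} out of range")
            if not 1 <= p <= self.max_passage:
                raise InvalidConfigError(f"contaminated passage {p} out of range")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["stromal_fraction_range"] = list(self.stromal_fraction_range)
        d["contaminated_passages"] = [list(x) for x in self.contaminated_passages]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        for key in ("maf_range", "stromal_fraction_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "contaminated_passages" in d:
            d["contaminated_passages"] = tuple(
                tuple(x) for x in d["contaminated_passages"]
            )
        return cls(**d)

    def initiation_drift(self, stability: StabilityClass) -> float:
        if stability is StabilityClass.UNSTABLE:
            return self.initiation_drift_unstable
        return self.initiation_drift_stable

    def passage_drift(self, passage: int, stability: StabilityClass) -> float:
        """Generative drift rate for passage ``passage`` (1-based)."""
        if passage == 1:
            return self.initiation_drift(stability)
        if passage == 7:
            return self.late_passage_drift
        return self.per_passage_drift


def derive_rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic per-stream generator: SeedSequence(seed, spawn_key)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


# ---------------------------------------------------------------------------
# markers


def simulate_markers(config: SimulationConfig) -> list[SnpMarker]:
    """Draw the candidate marker catalog.

    MAFs come from a three-component mixture spanning (0, 0.5] — rare
    (45%, U(0.001, 0.05)), intermediate (35%, U(0.05, lo)), and common
    (20%, U(lo, hi) over ``maf_range``) — so a realistic excess of rare
    exonic variants surrounds the common markers the panel will keep.
    Positions are strictly increasing within each of 22 autosomes.
    """
    rng = derive_rng(config.seed, _NS_MARKERS)
    n = config.n_candidate_markers
    lo, hi = config.maf_range
    component = rng.choice(3, size=n, p=(0.45, 0.35, 0.20))
    mafs = np.empty(n)
    mafs[component == 0] = rng.uniform(0.001, min(0.05, lo), (component == 0).sum())
    mafs[component == 1] = rng.uniform(min(0.05, lo), lo, (component == 1).sum())
    mafs[component == 2] = rng.uniform(lo, hi, (component == 2).sum())

    chrom_of = rng.integers(1, 23, size=n)
    gaps = rng.integers(200, 20_000, size=n)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)

    markers: list[SnpMarker] = []
    # strictly increasing positions per chromosome via per-chromosome cumsum
    order = np.argsort(chrom_of, kind="stable")
    pos = np.empty(n, dtype=np.int64)
    last_chrom, running = -1, 0
    for i in order:
        if chrom_of[i] != last_chrom:
            last_chrom, running = chrom_of[i], 0
        running += int(gaps[i])
        pos[i] = running
    for i in range(n):
        a, b = _ALLELE_PAIRS[allele_idx[i]]
        markers.append(
            SnpMarker(
                marker_id=f"snp{i + 1:07d}",
                chromosome=str(int(chrom_of[i])),
                position=int(pos[i]),
                allele_a=a,
                allele_b=b,
                maf=float(mafs[i]),
            )
        )
    return markers


# ---------------------------------------------------------------------------
# samples


def _hwe_calls(mafs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised Hardy-Weinberg genotype draw: P(BB)=q^2, P(AB)=2pq, P(AA)=p^2."""
    q = mafs
    p = 1.0 - q
    u = rng.random(mafs.size)
    calls = np.full(mafs.size, 2, dtype=np.int8)  # HOM_B
    calls[u < p * p + 2 * p * q] = 1  # HET
    calls[u < p * p] = 0  # HOM_A
    return calls


def simulate_patient_genotypes(
    panel: SnpPanel,
    seed: int | np.random.Generator,
    missing_rate: float = 0.0,
    sample_id: str = "PT",
) -> GenotypeVector:
    """Draw one individual's genotypes under Hardy-Weinberg proportions.

    Per marker with minor allele frequency ``q`` the genotype is HOM_A with
    probability ``(1-q)^2``, HET with ``2q(1-q)`` and HOM_B with ``q^2``;
    calls then go missing independently at ``missing_rate``.
    """
    if panel.size == 0:
        raise ValueError("panel is empty")
    rng = seed if isinstance(seed, np.random.Generator) else derive_rng(int(seed))
    calls = _hwe_calls(panel.mafs, rng)
    if missing_rate > 0:
        calls[rng.random(panel.size) < missing_rate] = MISSING
    return GenotypeVector(sample_id, calls)


def simulate_pdx_passage(
    parent: GenotypeVector,
    drift_rate: float,
    stromal_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    sample_id: str | None = None,
    stromal_missing_scale: float = 0.2,
) -> GenotypeVector:
    """Propagate a sample one passage with genotype drift and stromal dropout.

    Each non-missing parental call is independently altered with
    probability ``drift_rate``: HET becomes a random homozygote (LOH) and
    either homozygote becomes HET, so every alteration is a detectable
    genotype change. Mouse stromal admixture does not change genotype
    identity (human-specific probes do not cross-hybridise) but degrades
    the call rate: extra missingness ``stromal_missing_scale *
    stromal_fraction`` is applied to called sites.
    """
    if not 0.0 <= drift_rate <= 1.0:
        raise ValueError(f"drift_rate {drift_rate} outside [0, 1]")
    if not 0.0 <= stromal_fraction <= 1.0:
        raise ValueError(f"stromal_fraction {stromal_fraction} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else derive_rng(int(seed))
    calls = parent.calls.copy()
    called = calls != MISSING
    alter = called & (rng.random(calls.size) < drift_rate)
    het = alter & (calls == 1)
    hom = alter & ~het
    calls[hom] = 1
    calls[het] = rng.choice(np.array([0, 2], dtype=np.int8), size=int(het.sum()))
    extra_missing_rate = stromal_missing_scale * stromal_fraction
    if extra_missing_rate > 0:
        drop = called & (rng.random(calls.size) < extra_missing_rate)
        calls[drop] = MISSING
    return GenotypeVector(sample_id or f"{parent.sample_id}-child", calls)


def simulate_contaminated_sample(
    panel: SnpPanel,
    config: SimulationConfig,
    seed: int | np.random.Generator = 0,
    reference: GenotypeVector | None = None,
    sample_id: str = "CONTAMINATED",
) -> GenotypeVector:
    """Mimic a mouse-lymphoma sample assayed on the human SNP array.

    Mouse DNA mostly fails to genotype on human-specific probes, so the
    call rate collapses to ``contamination_call_rate``; the residual calls
    agree with the reference human sample only at the chance level
    ``contamination_match_rate`` — per called marker the call equals the
    reference genotype with that probability and is otherwise uniform over
    the two remaining states. With no ``reference`` given, an unrelated
    Hardy-Weinberg individual is drawn internally as the comparator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else derive_rng(int(seed))
    if reference is None:
        reference = simulate_patient_genotypes(panel, rng, sample_id="_unrelated")
    if len(reference) != panel.size:
        raise ValueError("reference vector not aligned to panel")
    n = panel.size
    calls = np.full(n, MISSING, dtype=np.int8)
    called = rng.random(n) < config.contamination_call_rate
    match = rng.random(n) < config.contamination_match_rate
    ref = reference.calls
    # where the reference itself is missing, fall back to a uniform call
    ref_known = ref != MISSING
    uniform = rng.integers(0, 3, size=n).astype(np.int8)
    # mismatching call: uniform over the two states != reference
    offset = rng.integers(1, 3, size=n).astype(np.int8)
    mismatch = ((ref + offset) % 3).astype(np.int8)
    calls[called & ref_known & match] = ref[called & ref_known & match]
    calls[called & ref_known & ~match] = mismatch[called & ref_known & ~match]
    calls[called & ~ref_known] = uniform[called & ~ref_known]
    return GenotypeVector(sample_id, calls)


# ---------------------------------------------------------------------------
# cohort


@dataclass(frozen=True)
class CohortManifest:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    config: SimulationConfig
    lineage_truth: tuple[dict, ...]
    duplicate_pairs: tuple[tuple[str, str], ...]
    contaminated_sample_ids: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "lineage_truth": [dict(t) for t in self.lineage_truth],
            "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            "contaminated_sample_ids": list(self.contaminated_sample_ids),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortManifest":
        return cls(
            config=SimulationConfig.from_dict(d["config"]),
            lineage_truth=tuple(dict(t) for t in d["lineage_truth"]),
            duplicate_pairs=tuple(tuple(p) for p in d["duplicate_pairs"]),
            contaminated_sample_ids=tuple(d["contaminated_sample_ids"]),
        )


@dataclass(frozen=True)
class Cohort:
    """A simulated study: panel, lineages, genotype vectors, ground truth."""

    panel: SnpPanel
    lineages: tuple[PdxLineage, ...]
    samples: dict[str, GenotypeVector]
    manifest: CohortManifest

    def sample(self, sample_id: str) -> GenotypeVector:
        return self.samples[sample_id]


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full synthetic cohort per the configuration.

    The first ``n_unstable`` lineages are UNSTABLE (initiation drift
    ``initiation_drift_unstable``), the rest STABLE; passages P2..P6 drift
    at ``per_passage_drift`` and P7 at ``late_passage_drift``. Requested
    contaminated passages are replaced by lymphoma-like samples generated
    against the lineage's PT; requested duplicates copy the PT with assay
    noise only. Byte-identical output for identical configuration.
    """
    markers = simulate_markers(config)
    panel = select_panel(
        markers, maf_threshold=config.maf_range[0], size=config.panel_size
    )
    contaminated_by_lineage: dict[int, set[int]] = {}
    for li, p in config.contaminated_passages:
        contaminated_by_lineage.setdefault(li, set()).add(p)

    lineages: list[PdxLineage] = []
    samples: dict[str, GenotypeVector] = {}
    truth: list[dict] = []
    duplicate_pairs: list[tuple[str, str]] = []
    contaminated_ids: list[str] = []

    for li in range(config.n_lineages):
        lineage_id = f"PDX-{li + 1:04d}"
        stability = (
            StabilityClass.UNSTABLE if li < config.n_unstable else StabilityClass.STABLE
        )
        brca = (
            BrcaStatus.MUTANT
            if stability is StabilityClass.UNSTABLE and li < 2
            else BrcaStatus.UNKNOWN
        )
        pt_id = f"{lineage_id}-PT"
        pt = simulate_patient_genotypes(
            panel,
            derive_rng(config.seed, _NS_PATIENT, li),
            missing_rate=config.missing_rate_base,
            sample_id=pt_id,
        )
        samples[pt_id] = pt

        stroma_rng = derive_rng(config.seed, _NS_STROMA, li)
        slo, shi = config.stromal_fraction_range
        stromal = stroma_rng.uniform(slo, shi, size=config.max_passage)

        passage_ids: list[str] = []
        drift_used: dict[int, float] = {}
        parent = pt
        for p in range(1, config.max_passage + 1):
            pid = f"{lineage_id}-P{p}"
            passage_ids.append(pid)
            d = config.passage_drift(p, stability)
            drift_used[p] = d
            child = simulate_pdx_passage(
                parent,
                drift_rate=d,
                stromal_fraction=float(stromal[p - 1]),
                seed=derive_rng(config.seed, _NS_PASSAGE, li, p),
                sample_id=pid,
                stromal_missing_scale=config.stromal_missing_scale,
            )
            recorded = child
            if p in contaminated_by_lineage.get(li, set()):
                # the recorded assay is lymphoma; propagation continues from
                # the underlying tumor so each contaminated passage is an
                # independently injected event under ground-truth control
                recorded = simulate_contaminated_sample(
                    panel,
                    config,
                    seed=derive_rng(config.seed, _NS_CONTAMINATION, li, p),
                    reference=pt,
                    sample_id=pid,
                )
                contaminated_ids.append(pid)
            samples[pid] = recorded
            parent = child

        lineages.append(
            PdxLineage(
                lineage_id=lineage_id,
                patient_sample_id=pt_id,
                passage_sample_ids=tuple(passage_ids),
                stability_class=stability,
                brca_status=brca,
                contaminated_passages=frozenset(
                    contaminated_by_lineage.get(li, set())
                ),
            )
        )
        truth.append(
            {
                "lineage_id": lineage_id,
                "stability_class": stability.value,
                "initiation_drift": config.initiation_drift(stability),
                "drift_by_passage": {str(k): v for k, v in drift_used.items()},
                "stromal_fractions": [float(s) for s in stromal],
            }
        )

    for li in range(config.n_duplicates):
        lineage = lineages[li]
        pt = samples[lineage.patient_sample_id]
        dup_id = f"{lineage.patient_sample_id}-DUP"
        dup = simulate_pdx_passage(
            pt,
            drift_rate=config.assay_noise_rate,
            stromal_fraction=0.0,
            seed=derive_rng(config.seed, _NS_DUPLICATE, li),
            sample_id=dup_id,
        )
        samples[dup_id] = dup
        duplicate_pairs.append((lineage.patient_sample_id, dup_id))

    manifest = CohortManifest(
        config=config,
        lineage_truth=tuple(truth),
        duplicate_pairs=tuple(duplicate_pairs),
        contaminated_sample_ids=tuple(contaminated_ids),
    )
    return Cohort(
        panel=panel, lineages=tuple(lineages), samples=samples, manifest=manifest
    )
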