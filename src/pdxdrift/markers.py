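"""SNP marker and panel containers.

A *marker* is one biallelic exonic SNP with a population minor allele
frequency (MAF); a *panel* is the ordered signature of such markers over
which every sample is genotyped and every pairwise statistic is computed.
The study design calls for common SNPs (MAF >= 0.40) so that unrelated
samples disagree often enough to be distinguishable from matched ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = frozenset("ACGT")

# natural chromosome order: 1..22, X, Y, MT, then anything else lexicographic
_CHROM_ORDER = {str(i): i for i in range(1, 23)}
_CHROM_ORDER.update({"X": 23, "Y": 24, "MT": 25, "M": 25})


def chromosome_sort_key(chromosome: str) -> tuple[int, str]:
    """Sort key giving the conventional 1..22, X, Y, MT genome order."""
    c = chromosome.removeprefix("chr")
    return (_CHROM_ORDER.get(c, 99), c)


@dataclass(frozen=True, slots=True)
class SnpMarker:
    """One biallelic SNP with its population minor allele frequency.

    ``allele_a`` is the major allele, ``allele_b`` the minor allele;
    ``position`` is 1-based, matching VCF convention.
    """

    marker_id: str
    chromosome: str
    position: int
    allele_a: str
    allele_b: str
    maf: float

    def __post_init__(self) -> None:
        if self.allele_a not in _BASES or self.allele_b not in _BASES:
            raise ValueError(
                f"marker {self.marker_id}: alleles must be single bases, "
                f"got {self.allele_a!r}/{self.allele_b!r}"
            )
        if self.allele_a == self.allele_b:
            raise ValueError(f"marker {self.marker_id}: alleles must differ")
        if self.position < 1:
            raise ValueError(f"marker {self.marker_id}: position must be >= 1")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(
                f"marker {self.marker_id}: maf {self.maf} outside [0, 0.5]"
            )


@dataclass(frozen=True)
class SnpPanel:
    """An ordered, duplicate-free signature of SNP markers.

    All genotype vectors in the pipeline are aligned to a panel's marker
    order; ``mafs`` is exposed as an array for vectorised simulation.
    """

    markers: tuple[SnpMarker, ...]
    maf_threshold: float | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __init__(
        self,
        markers,
        maf_threshold: float | None = None,
    ) -> None:
        object.__setattr__(self, "markers", tuple(markers))
        object.__setattr__(self, "maf_threshold", maf_threshold)
        index = {m.marker_id: i for i, m in enumerate(self.markers)}
        if len(index) != len(self.markers):
            seen: set[str] = set()
            dup = next(
                m.marker_id
                for m in self.markers
                if m.marker_id in seen or seen.add(m.marker_id)
            )
            raise ValueError(f"duplicate marker id in panel: {dup}")
        if maf_threshold is not None:
            for m in self.markers:
                if m.maf < maf_threshold:
                    raise ValueError(
                        f"marker {m.marker_id} maf {m.maf} below panel "
                        f"threshold {maf_threshold}"
                    )
        object.__setattr__(self, "_index", index)

    @property
    def size(self) -> int:
        return len(self.markers)

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    def __getitem__(self, i: int) -> SnpMarker:
        return self.markers[i]

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    @property
    def mafs(self) -> np.ndarray:
        return np.array([m.maf for m in self.markers], dtype=float)

    def index_of(self, marker_id: str) -> int:
        return self._index[marker_id]

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self._index
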