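"""Genotype call encoding and per-sample call vectors.

Calls are stored as a compact int8 array: 0 = homozygous major (AA),
1 = heterozygous (AB), 2 = homozygous minor (BB), -1 = missing/no-call.
Heterozygotes are unordered (A/B is the same state as B/A).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

MISSING: int = -1


class GenotypeCall(enum.IntEnum):
    """One genotype state over a biallelic marker."""

    HOM_A = 0
    HET = 1
    HOM_B = 2
    MISSING = -1


_VALID_CODES = frozenset({0, 1, 2, -1})


def as_call_array(calls) -> np.ndarray:
    """Coerce a call sequence to a validated int8 array."""
    arr = np.asarray(calls, dtype=np.int8)
    if arr.ndim != 1:
        raise ValueError(f"calls must be 1-D, got shape {arr.shape}")
    bad = ~np.isin(arr, (-1, 0, 1, 2))
    if bad.any():
        raise ValueError(f"invalid genotype code {arr[bad][0]} at index {int(np.flatnonzero(bad)[0])}")
    return arr


@dataclass(frozen=True)
class GenotypeVector:
    """One sample's ordered genotype calls over a panel.

    The vector carries no marker identity of its own; alignment to a panel's
    marker order is the caller's contract and is validated on I/O.
    """

    sample_id: str
    calls: np.ndarray = field(compare=False)

    def __init__(self, sample_id: str, calls) -> None:
        object.__setattr__(self, "sample_id", sample_id)
        arr = as_call_array(calls)
        arr.setflags(write=False)
        object.__setattr__(self, "calls", arr)

    def __len__(self) -> int:
        return self.calls.size

    @property
    def called_mask(self) -> np.ndarray:
        return self.calls != MISSING

    @property
    def n_called(self) -> int:
        return int(self.called_mask.sum())

    @property
    def call_rate(self) -> float:
        """Fraction of panel markers with a non-missing call."""
        if self.calls.size == 0:
            return 0.0
        return self.n_called / self.calls.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeVector):
            return NotImplemented
        return self.sample_id == other.sample_id and np.array_equal(
            self.calls, other.calls
        )

    def __hash__(self) -> int:
        return hash((self.sample_id, self.calls.tobytes()))
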