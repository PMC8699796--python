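"""Signature panel selection: MAF estimation and high-MAF marker filtering.

The discriminating power of a fingerprinting panel comes from common
variants: at MAF >= 0.40 two unrelated individuals share a genotype at only
~38% of sites under Hardy-Weinberg proportions, while a matched pair agrees
at nearly all sites, so a 300-marker signature separates the two regimes by
a wide margin.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np

from .genotypes import MISSING
from .markers import SnpMarker, SnpPanel, chromosome_sort_key

DEFAULT_MAF_THRESHOLD = 0.40
DEFAULT_PANEL_SIZE = 300
DEFAULT_MIN_CALL_RATE = 0.95


class PanelSelectionError(ValueError):
    """Raised when a panel cannot be assembled from the qualifying markers."""


def compute_maf(calls_matrix) -> np.ndarray:
    """Estimate per-marker minor allele frequency from a genotype matrix.

    Parameters
    ----------
    calls_matrix : array-like of shape (n_samples, n_markers)
        Genotype codes 0/1/2 with -1 for missing. Missing calls are
        excluded from the allele counts.

    Returns
    -------
    numpy.ndarray
        Per-marker MAF, ``min(f_B, 1 - f_B)`` where
        ``f_B = (2*n_homB + n_het) / (2*n_called)``. Markers with zero
        called genotypes are flagged as ``nan``.
    """
    m = np.asarray(calls_matrix)
    if m.ndim != 2:
        raise ValueError("calls_matrix must be 2-D (samples x markers)")
    called = m != MISSING
    n_called = called.sum(axis=0)
    n_het = ((m == 1) & called).sum(axis=0)
    n_hom_b = ((m == 2) & called).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_b = (2.0 * n_hom_b + n_het) / (2.0 * n_called)
    maf = np.minimum(f_b, 1.0 - f_b)
    maf[n_called == 0] = np.nan
    return maf


def select_panel(
    markers: Sequence[SnpMarker],
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
    size: int = DEFAULT_PANEL_SIZE,
    min_call_rate: float = DEFAULT_MIN_CALL_RATE,
    call_rates: Sequence[float] | None = None,
) -> SnpPanel:
    """Select a fixed-size signature of common markers.

    Markers must satisfy ``maf >= maf_threshold`` (inclusive, "at least
    40%") and, when per-marker call rates over a reference sample set are
    supplied, ``call_rate >= min_call_rate``. Among qualifying markers the
    top ``size`` are taken by descending MAF with (chromosome, position) as
    a deterministic tie-break; the returned panel is ordered genomically.

    Raises
    ------
    PanelSelectionError
        If fewer than ``size`` markers qualify; the message reports the
        qualifying count.
    """
    if call_rates is not None and len(call_rates) != len(markers):
        raise ValueError(
            f"call_rates length {len(call_rates)} != markers length {len(markers)}"
        )
    qualifying = []
    for i, mk in enumerate(markers):
        if mk.maf < maf_threshold:
            continue
        if call_rates is not None and call_rates[i] < min_call_rate:
            continue
        qualifying.append(mk)
    if len(qualifying) < size:
        raise PanelSelectionError(
            f"cannot select panel of {size} markers at MAF >= {maf_threshold}: "
            f"only {len(qualifying)} qualifying"
        )
    qualifying.sort(
        key=lambda m: (-m.maf, chromosome_sort_key(m.chromosome), m.position)
    )
    selected = qualifying[:size]
    selected.sort(key=lambda m: (chromosome_sort_key(m.chromosome), m.position))
    return SnpPanel(selected, maf_threshold=maf_threshold)
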