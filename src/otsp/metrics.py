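"""Repertoire summary metrics on (normalized) clonotype tables.

All metrics are functions of the clonotype relative frequencies only, so
they are invariant under any uniform rescaling of counts; primer-pair
normalization changes them exactly through the relative weights it moves
between pairs. Definitions (natural log throughout):

* Shannon diversity  H = -sum p_k ln p_k, in [0, ln S];
* clonality          1 - H / ln S (evenness complement: 0 even, 1 monoclonal);
* maximum clonal frequency  max_k p_k;
* hyperexpanded fraction    sum of p_k over clones with p_k > threshold
  (default threshold 0.01).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_HYPEREXPANDED_THRESHOLD = 0.01


def clonal_frequencies(counts) -> np.ndarray:
    """Relative frequencies from positive clone counts (zeros dropped)."""
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise ValueError("empty clonotype counts")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    c = c[c > 0]
    total = c.sum()
    if total == 0:
        raise ValueError("all counts are zero")
    return c / total


def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.size == 0:
        raise ValueError("empty frequency vector")
    if np.any(p <= 0):
        raise ValueError("frequencies must be strictly positive")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    return p


def shannon_diversity(freqs) -> float:
    """H = -sum p ln p."""
    p = _check_freqs(freqs)
    return float(-np.sum(p * np.log(p)))


def clonality(freqs) -> float:
    """1 - H/ln S; degenerate single-clone repertoires are maximally clonal."""
    p = _check_freqs(freqs)
    if p.size == 1:
        warnings.warn("single-clone repertoire: clonality defined as 1")
        return 1.0
    return float(1.0 - shannon_diversity(p) / np.log(p.size))


def max_clonal_frequency(freqs) -> float:
    return float(np.max(_check_freqs(freqs)))


def hyperexpanded_fraction(
    freqs, threshold: float = DEFAULT_HYPEREXPANDED_THRESHOLD
) -> float:
    """Total frequency carried by clones with p > threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    p = _check_freqs(freqs)
    return float(p[p > threshold].sum())


def repertoire_metrics(
    table: pd.DataFrame,
    threshold: float = DEFAULT_HYPEREXPANDED_THRESHOLD,
    use_normalized: bool | None = None,
) -> dict:
    """All four metrics for one clonotype table.

    Uses ``normalized_count`` when present (or when forced with
    ``use_normalized``), else raw ``count``.
    """
    if use_normalized is None:
        use_normalized = "normalized_count" in table.columns
    col = "normalized_count" if use_normalized else "count"
    if col not in table.columns:
        raise ValueError(f"column {col!r} not in clonotype table")
    counts = table[col].to_numpy(dtype=float)
    counts = counts[~np.isnan(counts)]
    p = clonal_frequencies(counts)
    return {
        "n_clonotypes": int(p.size),
        "shannon_diversity": shannon_diversity(p),
        "clonality": clonality(p),
        "max_clonal_frequency": max_clonal_frequency(p),
        "hyperexpanded_fraction": hyperexpanded_fraction(p, threshold),
    }
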