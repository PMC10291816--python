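"""Amplification-bias normalization of clonotype and ST counts.

Counts are first aggregated to primer-pair totals ``C_i`` (every clonotype
is amplified by exactly one V-primer/J-primer pair), the totals are divided
by the pair's scaling factor, and each clonotype then receives the same
proportion ``p`` of the normalized pair total that it held of the raw one.
Within-pair proportions — and therefore ranks and ratios — are untouched;
only the relative weight *between* primer pairs changes. Normalized counts
stay real-valued: re-rounding would break the exact preservation identities
(batch-mean self-normalization preserves the grand total exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demux import template_multiindex
from .scaling import ScalingFactorSet

REQUIRED_COLUMNS = ("cdr3_nt", "v_gene", "j_gene", "count")


@dataclass(frozen=True)
class PrimerMap:
    """Gene-name → primer-index maps (possibly many-to-one: one V primer can
    amplify several V segments)."""

    v_map: dict
    j_map: dict
    n_v: int = 20
    n_j: int = 13

    def __post_init__(self):
        if len(set(self.v_map.values())) > self.n_v:
            raise ValueError(f"more than {self.n_v} distinct V primer indices")
        if len(set(self.j_map.values())) > self.n_j:
            raise ValueError(f"more than {self.n_j} distinct J primer indices")
        for idx in self.v_map.values():
            if not 1 <= idx <= self.n_v:
                raise ValueError(f"V primer index {idx} out of range")
        for idx in self.j_map.values():
            if not 1 <= idx <= self.n_j:
                raise ValueError(f"J primer index {idx} out of range")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clonotype table lacks columns: {missing}")
    if (table["count"] < 0).any():
        raise ValueError("clonotype counts must be non-negative")


def _pair_index(table: pd.DataFrame, pmap: PrimerMap):
    """Per-record (v_index, j_index), NaN where a gene is unmapped."""
    v = table["v_gene"].map(pmap.v_map)
    j = table["j_gene"].map(pmap.j_map)
    return v, j


def primer_pair_totals(
    table: pd.DataFrame, pmap: PrimerMap
) -> tuple[pd.Series, pd.DataFrame]:
    """Aggregate clonotype counts to the 260 primer-pair totals ``C_i``.

    Returns (totals indexed by (v_index, j_index), unmapped records).
    Unmapped records are excluded from normalization and reported back.
    """
    _check_table(table)
    totals = pd.Series(
        0.0, index=template_multiindex(pmap.n_v, pmap.n_j), name="total"
    )
    if len(table) == 0:
        return totals, table.copy()
    v, j = _pair_index(table, pmap)
    mapped = v.notna() & j.notna()
    unmapped = table.loc[~mapped].copy()
    sub = table.loc[mapped]
    if len(sub):
        grouped = sub.groupby(
            [v[mapped].astype(int), j[mapped].astype(int)]
        )["count"].sum()
        grouped.index.names = ["v_index", "j_index"]
        totals.loc[grouped.index] = grouped.astype(float)
    return totals, unmapped


def normalize_totals(totals: pd.Series, factors: ScalingFactorSet) -> pd.Series:
    """Divide primer-pair totals by their scaling factors:
    ``C_i' = C_i / SF_i`` (equivalently ``C_i'' = (m_. / m_i) C_i``)."""
    f = factors.factors.reindex(totals.index)
    if f.isna().any():
        raise ValueError("scaling factors missing for some primer pairs")
    bad = (totals > 0) & ~(f > 0)
    if bad.any():
        pairs = list(totals.index[bad])[:5]
        raise ValueError(
            f"nonzero totals at pairs with unusable (zero) factors: {pairs}"
        )
    out = totals.astype(float).copy()
    pos = f > 0
    out[pos] = totals[pos] / f[pos]
    return out


def reallocate_clonotypes(
    table: pd.DataFrame, normalized_totals: pd.Series, pmap: PrimerMap
) -> pd.DataFrame:
    """Assign each clonotype its raw within-pair proportion of the
    normalized pair total; adds a ``normalized_count`` column.

    Unmapped records get NaN. Per-pair sums of normalized counts equal the
    normalized totals exactly and within-pair ratios are preserved.
    """
    _check_table(table)
    out = table.copy()
    out["normalized_count"] = np.nan
    if len(table) == 0:
        return out
    v, j = _pair_index(table, pmap)
    mapped = v.notna() & j.notna()
    raw_totals, _ = primer_pair_totals(table, pmap)
    keys = list(zip(v[mapped].astype(int), j[mapped].astype(int)))
    raw = raw_totals.loc[keys].to_numpy()
    norm = normalized_totals.loc[keys].to_numpy()
    counts = out.loc[mapped, "count"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(raw > 0, counts * (norm / np.where(raw > 0, raw, 1.0)), 0.0)
    out.loc[mapped, "normalized_count"] = scaled
    return out


def normalize_clonotypes(
    table: pd.DataFrame, factors: ScalingFactorSet, pmap: PrimerMap
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full normalization: totals → rescale → reallocate.

    Returns (table with ``normalized_count``, unmapped records).
    """
    totals, unmapped = primer_pair_totals(table, pmap)
    normalized = normalize_totals(totals, factors)
    return reallocate_clonotypes(table, normalized, pmap), unmapped


def normalize_st_counts(
    matrix: pd.DataFrame, factors: ScalingFactorSet
) -> pd.DataFrame:
    """Columnwise division of an ST count matrix by the scaling factors."""
    f = factors.factors.reindex(matrix.index)
    if f.isna().any():
        raise ValueError("scaling factors missing for some templates")
    bad = (matrix.sum(axis=1) > 0) & ~(f > 0)
    if bad.any():
        raise ValueError(
            f"nonzero counts at templates with unusable (zero) factors: "
            f"{list(matrix.index[bad])[:5]}"
        )
    out = matrix.astype(float).copy()
    pos = f > 0
    out.loc[pos] = out.loc[pos].div(f[pos], axis=0)
    return out
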