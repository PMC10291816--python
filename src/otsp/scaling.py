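"""Per-primer-pair scaling factors from synthetic-template counts.

Two equivalent estimators of the same amplification-bias profile:

* batch-mean factors ``SF_i = C_i. / C_..`` where ``C_i.`` is the batch
  mean count of template i and ``C_..`` the mean of the 260 batch means;
* NB-mean factors ``m_i / m_.`` from per-template negative-binomial fits.

Because the NB mean MLE *is* the arithmetic mean, the two coincide exactly
when computed from the same matrix; both average to 1 by construction.
Factors estimated at different spike-in concentrations are pooled by
reducing each batch to relative frequencies first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ScalingFactorSet:
    """260 per-primer-pair factors with mean exactly 1.

    ``factors`` is indexed by (v_index, j_index). Templates whose estimated
    mean is zero keep their zero factor (so the mean-1 identity holds) but
    are flagged unusable; normalizing a nonzero count with an unusable
    factor is an error, never a silent division by zero.
    """

    factors: pd.Series
    method: str  # "batch_mean" | "nb_mean" | "combined" | "true"
    source_batches: tuple = ()

    def __post_init__(self):
        f = np.asarray(self.factors, dtype=float)
        if np.any(f < 0):
            raise ValueError("scaling factors cannot be negative")

    @property
    def usable(self) -> pd.Series:
        return self.factors > 0

    def __len__(self) -> int:
        return len(self.factors)


def _row_means(matrix: pd.DataFrame) -> pd.Series:
    m = matrix.mean(axis=1)
    if float(m.sum()) == 0.0:
        raise ValueError("all-zero count matrix: no scale defined")
    return m


def batch_mean_scaling_factors(matrix: pd.DataFrame) -> ScalingFactorSet:
    """``SF_i = C_i. / C_..`` from one batch's ST count matrix."""
    row_means = _row_means(matrix)
    grand = row_means.mean()
    return ScalingFactorSet(row_means / grand, method="batch_mean")


def nb_mean_scaling_factors(fits: pd.DataFrame) -> ScalingFactorSet:
    """``m_i / m_.`` from per-template NB fits (see :func:`otsp.nb.fit_matrix`)."""
    m = fits["m"].astype(float)
    grand = m.mean()
    if grand == 0.0:
        raise ValueError("all fitted means are zero: no scale defined")
    return ScalingFactorSet(m / grand, method="nb_mean")


def nb_mean_scaling_factors_from_matrix(matrix: pd.DataFrame) -> ScalingFactorSet:
    """NB-mean factors straight from a count matrix via the closed-form
    mean MLE ``m̂_i = C_i.`` (the NB mean MLE is the arithmetic mean, so no
    dispersion fit is needed to obtain the factors)."""
    row_means = _row_means(matrix)
    return ScalingFactorSet(row_means / row_means.mean(), method="nb_mean")


def combine_batches(mean_vectors: list[pd.Series], weights) -> pd.Series:
    """Pool per-template mean estimates across batches run at different
    spike-in concentrations.

    Each batch vector is reduced to relative frequencies (dividing by its
    own sum removes the overall concentration/depth difference), the
    frequencies are averaged with weights proportional to each batch's
    sample count, and the result is rescaled so its mean equals the
    weighted mean of the batch grand means. Scaling factors derived from
    the combined vector are invariant to any positive rescaling of a batch.
    """
    if len(mean_vectors) == 0:
        raise ValueError("need at least one batch")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(mean_vectors) or np.any(w <= 0):
        raise ValueError("need one positive weight per batch")
    freqs = []
    grand_means = []
    for vec in mean_vectors:
        v = vec.astype(float)
        total = float(v.sum())
        if total <= 0:
            raise ValueError("zero-sum batch mean vector")
        freqs.append(v / total)
        grand_means.append(v.mean())
    f_comb = sum(wi * fi for wi, fi in zip(w, freqs)) / w.sum()
    m_bar = float(np.dot(w, grand_means) / w.sum())
    n_templates = len(mean_vectors[0])
    return f_comb * n_templates * m_bar


def scaling_concordance(a: ScalingFactorSet, b: ScalingFactorSet) -> float:
    """Pearson correlation of log factors between two sets (cross-batch
    stability measure)."""
    fa = np.asarray(a.factors, dtype=float)
    fb = np.asarray(b.factors, dtype=float)
    if fa.shape != fb.shape:
        raise ValueError("factor sets must have equal length")
    if np.any(fa <= 0) or np.any(fb <= 0):
        raise ValueError("concordance requires strictly positive factors")
    r, _ = stats.pearsonr(np.log(fa), np.log(fb))
    return float(r)
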