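"""V×J primer dependence from pooled synthetic-template counts.

Each primer pair shares its V primer with 12 other pairs and its J primer
with 19 others, so pair counts need not be independent. Departures from
row-column independence of the pooled 20×13 count table are measured as
signed Pearson residuals ``(O - E) / sqrt(E)`` with ``E = row total ×
column total / grand total``; their squared sum is the chi-squared
statistic. A Monte-Carlo null (iid NB counts, no bias, self-normalized)
provides the spread achievable in the *absence* of dependence, the lower
bound against which observed bias reduction is judged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .scaling import batch_mean_scaling_factors


def pooled_vj_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum an ST count matrix over samples into a V×J table ``O``."""
    pooled = matrix.sum(axis=1)
    table = pooled.unstack("j_index")
    table.index.name = "v_index"
    return table


def pearson_residuals(table: pd.DataFrame) -> pd.DataFrame:
    """Signed Pearson residuals ``(O - E)/sqrt(E)`` under independence.

    Cells in zero-margin rows/columns are undefined (NaN); the expected
    table sums to the grand total exactly.
    """
    O = table.to_numpy(dtype=float)
    if np.any(O < 0):
        raise ValueError("counts must be non-negative")
    grand = O.sum()
    if grand <= 0:
        raise ValueError("grand total must be positive")
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    E = row @ col / grand
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (O - E) / np.sqrt(E)
    R[E == 0] = np.nan
    return pd.DataFrame(R, index=table.index, columns=table.columns)


def chi_squared(table: pd.DataFrame) -> float:
    """Sum of squared Pearson residuals over defined cells."""
    r = pearson_residuals(table).to_numpy()
    return float(np.nansum(r**2))


def _leaf_order(mat: np.ndarray) -> np.ndarray:
    if mat.shape[0] < 2:
        return np.arange(mat.shape[0])
    dists = pdist(mat, metric="euclidean")
    if np.allclose(dists, dists[0]):
        # all profiles equidistant (e.g. all-zero residuals): keep input order
        return np.arange(mat.shape[0])
    link = hierarchy.linkage(dists, method="average")
    return np.asarray(hierarchy.leaves_list(link))


def cluster_residuals(residuals: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage hierarchical orderings of rows and columns for
    heatmap display; deterministic, with degenerate (equidistant) input
    keeping its original order. NaN cells are treated as 0 for distances."""
    R = residuals.to_numpy(dtype=float)
    R = np.nan_to_num(R, nan=0.0)
    return _leaf_order(R), _leaf_order(R.T)


def independence_null_spread(
    m: float,
    d: float,
    n_templates: int = 260,
    n_samples: int = 20,
    reps: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo null for the within-sample spread of self-normalized
    counts when all templates are iid NB(m, d) — i.e. equimolar, unbiased
    and independent.

    Per replicate: draw an ``n_templates × n_samples`` iid NB matrix,
    normalize it by its own batch-mean factors, and record two spread
    statistics averaged over samples: the log max/min ratio and the IQR of
    log counts (zero counts are excluded from both; keep ``m`` large enough
    that they are rare). Returns one row per replicate.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if m <= 0:
        raise ValueError("m must be > 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        if d == 0:
            counts = rng.poisson(m, size=(n_templates, n_samples)).astype(float)
        else:
            r = 1.0 / d
            p = 1.0 / (1.0 + d * m)
            counts = rng.negative_binomial(r, p, size=(n_templates, n_samples)).astype(float)
        factors = counts.mean(axis=1)
        grand = factors.mean()
        if grand == 0:
            raise ValueError("all-zero replicate; increase m")
        pos = factors > 0  # all-zero rows carry no usable factor
        norm = counts[pos] / (factors[pos] / grand)[:, None]
        log_ratios = []
        iqrs = []
        for j in range(n_samples):
            col = norm[:, j]
            col = col[col > 0]
            logs = np.log(col)
            log_ratios.append(logs.max() - logs.min())
            q75, q25 = np.percentile(logs, [75, 25])
            iqrs.append(q75 - q25)
        rows.append(
            {
                "rep": rep,
                "log_max_min_ratio": float(np.mean(log_ratios)),
                "iqr_log": float(np.mean(iqrs)),
            }
        )
    return pd.DataFrame(rows)
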