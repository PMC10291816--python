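"""Negative-binomial modeling of synthetic-template replicate counts.

The count ``C`` of one template across replicate samples is modeled as
``C ~ NB(m, d)`` in the mean/over-dispersion parameterization

    E(C) = m,   var(C) = m + d * m**2,

so ``d`` is the reciprocal of the conventional "size" and ``d = 0`` is the
Poisson. The mean MLE is the arithmetic mean of the counts, exactly; the
dispersion MLE maximizes the profile likelihood in ``d`` with ``m`` fixed
at the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

#: upper bound for the dispersion search; CVs beyond sqrt(d) ~ 7 are far
#: outside anything replicate spike-in counts produce
D_MAX = 50.0


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    return c


def nb_loglik(counts, m: float, d: float) -> float:
    """Log-likelihood of iid NB(m, d) counts; exact Poisson at d = 0.

    For integer counts the Gamma-ratio term ``lgamma(k + 1/d) - lgamma(1/d)``
    is accumulated as ``sum_{j<k} log(1/d + j)``, which stays accurate for
    arbitrarily small ``d`` (where the two lgamma values are astronomically
    large and their scipy difference loses precision).
    """
    c = _as_counts(counts)
    if m <= 0:
        raise ValueError("mean parameter m must be > 0")
    if d < 0:
        raise ValueError("dispersion d must be >= 0")
    c = c.astype(np.float64)
    if d == 0.0:
        return float(np.sum(c * np.log(m) - m - special.gammaln(c + 1)))
    r = 1.0 / d
    kmax = int(c.max())
    is_integer = np.all(c == np.floor(c))
    if is_integer and kmax <= 2_000_000:
        cum = np.concatenate([[0.0], np.cumsum(np.log(r + np.arange(kmax)))])
        gamma_ratio = cum[c.astype(np.int64)]
    else:  # non-integer or huge counts: plain lgamma difference
        gamma_ratio = special.gammaln(c + r) - special.gammaln(r)
    log1p_md = np.log1p(m * d)
    ll = (
        gamma_ratio
        - special.gammaln(c + 1)
        + c * (np.log(m) + np.log(d) - log1p_md)
        - r * log1p_md
    )
    return float(np.sum(ll))


@dataclass
class NBFit:
    m: float
    d: float
    n: int
    converged: bool
    log_likelihood: float
    degenerate: bool = False


def fit_nb(counts) -> NBFit:
    """Maximum-likelihood NB fit to a replicate count set.

    ``m`` is the arithmetic mean (the closed-form MLE); ``d`` maximizes the
    profile log-likelihood on [0, D_MAX] by bounded scalar optimization, with
    the Poisson boundary d = 0 checked explicitly. All-zero input is
    degenerate (m = d = 0).
    """
    c = _as_counts(counts)
    if c.size < 2:
        raise ValueError("need at least 2 replicate counts")
    m = float(np.mean(c))
    if m == 0.0:
        return NBFit(0.0, 0.0, c.size, True, 0.0, degenerate=True)
    v = float(np.var(c, ddof=1))
    if v == 0.0:
        return NBFit(m, 0.0, c.size, True, nb_loglik(c, m, 0.0))

    def nll(d):
        return -nb_loglik(c, m, d)

    res = optimize.minimize_scalar(nll, bounds=(0.0, D_MAX), method="bounded",
                                   options={"xatol": 1e-8})
    d_hat, ll = float(res.x), -float(res.fun)
    ll0 = nb_loglik(c, m, 0.0)
    if ll0 >= ll:  # boundary (Poisson) beats the interior optimum
        d_hat, ll = 0.0, ll0
    return NBFit(m, d_hat, c.size, bool(res.success), ll)


def fit_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise NB fits of an ST count matrix (rows = templates)."""
    rows = []
    for key, row in matrix.iterrows():
        fit = fit_nb(row.to_numpy())
        rows.append(
            {
                "m": fit.m,
                "d": fit.d,
                "n": fit.n,
                "converged": fit.converged,
                "log_likelihood": fit.log_likelihood,
                "degenerate": fit.degenerate,
            }
        )
    return pd.DataFrame(rows, index=matrix.index)


def common_dispersion(matrix: pd.DataFrame) -> float:
    """Median of per-template dispersion MLEs across the matrix rows.

    Degenerate rows (all-zero) are excluded with a warning; they carry no
    dispersion information.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate dispersion")
    fits = fit_matrix(matrix)
    usable = fits.loc[~fits["degenerate"], "d"]
    n_dropped = int(fits["degenerate"].sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} degenerate (all-zero) rows excluded "
                      "from the common-dispersion median")
    if usable.empty:
        raise ValueError("no usable rows for dispersion estimation")
    return float(usable.median())


def mean_variance_table(matrix: pd.DataFrame, d: float) -> pd.DataFrame:
    """Per-row empirical mean/variance and the NB prediction m + d*m^2."""
    if d < 0:
        raise ValueError("dispersion d must be >= 0")
    mean = matrix.mean(axis=1)
    var = matrix.var(axis=1, ddof=1)
    predicted = mean + d * mean**2
    return pd.DataFrame(
        {"mean": mean, "variance": var, "predicted_variance": predicted}
    )
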