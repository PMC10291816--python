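"""Diagnostic plots: mean-variance fit and the V×J residual heatmap."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns


def mean_variance_plot(table: pd.DataFrame, d: float, ax=None):
    """Log-log empirical variance vs mean with the NB line v = m + d m²."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pos = (table["mean"] > 0) & (table["variance"] > 0)
    ax.scatter(table.loc[pos, "mean"], table.loc[pos, "variance"], s=8, alpha=0.6)
    grid = np.geomspace(table.loc[pos, "mean"].min(), table.loc[pos, "mean"].max(), 200)
    ax.plot(grid, grid + d * grid**2, color="red", label=f"v = m + {d:g}·m²")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("mean")
    ax.set_ylabel("variance")
    ax.legend()
    return ax


def residual_heatmap(residuals: pd.DataFrame, orders=None, ax=None):
    """Signed Pearson-residual heatmap, optionally reordered by clustering."""
    R = residuals
    if orders is not None:
        row_order, col_order = orders
        R = R.iloc[row_order, col_order]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 7))
    vmax = float(np.nanmax(np.abs(R.to_numpy()))) or 1.0
    sns.heatmap(R, cmap="RdBu_r", center=0, vmin=-vmax, vmax=vmax, ax=ax,
                cbar_kws={"label": "Pearson residual"})
    ax.set_xlabel("J primer")
    ax.set_ylabel("V primer")
    return ax
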