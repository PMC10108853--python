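"""Scatter plots with least-squares regression lines and 95% bands."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps


def regression_scatter(
    table: pd.DataFrame,
    var_x: str,
    var_y: str,
    path: str | Path | None = None,
    ax: plt.Axes | None = None,
) -> plt.Axes:
    """Scatter of two cohort variables with the least-squares line and the
    95% confidence band of the mean prediction; annotates Pearson r and p."""
    sub = table[[var_x, var_y]].dropna()
    x = sub[var_x].to_numpy(float)
    y = sub[var_y].to_numpy(float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete observations to plot")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3.2))
    ax.plot(x, y, "o", color="0.35", ms=5)

    slope, intercept = np.polyfit(x, y, 1)
    xx = np.linspace(x.min(), x.max(), 100)
    yy = intercept + slope * xx
    resid = y - (intercept + slope * x)
    s_err = np.sqrt(np.sum(resid**2) / (n - 2))
    t_crit = sps.t.ppf(0.975, n - 2)
    half = t_crit * s_err * np.sqrt(1 / n + (xx - x.mean()) ** 2 / np.sum((x - x.mean()) ** 2))
    ax.plot(xx, yy, color="seagreen")
    ax.fill_between(xx, yy - half, yy + half, color="seagreen", alpha=0.2, lw=0)

    r, p = sps.pearsonr(x, y)
    ax.annotate(f"r = {r:.2f}\np = {p:.3f}", xy=(0.04, 0.96),
                xycoords="axes fraction", va="top", fontsize=9)
    ax.set_xlabel(var_x)
    ax.set_ylabel(var_y)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
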