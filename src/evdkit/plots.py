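"""Standard figures: stacked response curves, EVD exceedance curves, and
the stressor-ranking bar chart."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .curves import ResponseCurve
from .evd import EVD
from .overlay import CLASSES


def plot_response_curves(
    curves: Sequence[ResponseCurve],
    env_values: np.ndarray | None = None,
    band_quantiles: tuple[float, float] = (0.05, 0.95),
    ax=None,
):
    """One stressor's per-site RSR curves with points of departure and,
    when regional values are given, the shaded band outside the central
    stressor-level variability."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for c in curves:
        ax.plot(c.grid, c.rsr, lw=0.8, alpha=0.7)
        ax.plot([c.observed_value], [1.0], "o", ms=4, color="tab:blue")
    if env_values is not None and len(env_values):
        lo, hi = np.quantile(np.asarray(env_values, float), band_quantiles)
        ax.axvspan(ax.get_xlim()[0], lo, color="0.9", zorder=0)
        ax.axvspan(hi, ax.get_xlim()[1], color="0.9", zorder=0)
    ax.axhline(1.0, color="0.5", lw=0.5, ls=":")
    ax.set_xlabel(curves[0].stressor if curves else "stressor")
    ax.set_ylabel("relative species richness")
    return ax


def plot_evd(evd: EVD, env_values: np.ndarray | None = None,
             band_quantiles: tuple[float, float] = (0.05, 0.95), ax=None):
    """Exceedance curve of one EVD with the regional median and band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    lo, hi = evd.range
    pad = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - pad, hi + pad, 400)
    ax.step(grid, evd.exceedance(grid), where="post", color="tab:red")
    if env_values is not None and len(env_values):
        vals = np.asarray(env_values, float)
        ax.axvline(np.median(vals), color="tab:blue", lw=1.2)
        for q in np.quantile(vals, band_quantiles):
            ax.axvline(q, color="0.4", lw=0.8, ls=":")
    ax.set_xlabel(f"{evd.stressor} ({evd.direction})")
    ax.set_ylabel("fraction of reference sites exceeded")
    ax.set_ylim(-0.02, 1.02)
    return ax


def plot_ranking(ranking: pd.DataFrame, ax=None):
    """Stacked horizontal bars of not-at-risk / at-risk / impacted fractions,
    ordered by rank."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.5 * len(ranking) + 1.5))
    labels = [f"{r.stressor} ({r.direction})" for r in ranking.itertuples()]
    left = np.zeros(len(ranking))
    colors = {"not_at_risk": "tab:green", "at_risk": "gold", "impacted": "tab:red"}
    for cls, col in zip(CLASSES, ["f_not_at_risk", "f_at_risk", "f_impacted"]):
        vals = ranking[col].to_numpy(float)
        ax.barh(labels, vals, left=left, color=colors[cls], label=cls.replace("_", " "))
        left += vals
    ax.invert_yaxis()
    ax.set_xlabel("fraction of regional sites")
    ax.legend(fontsize=8, loc="lower right")
    return ax
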