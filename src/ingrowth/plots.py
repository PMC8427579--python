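"""Optional figure outputs mirroring the effect-summary presentation.

Each function takes the tabular output of :mod:`ingrowth.effects` and returns
a matplotlib Figure; callers save in whatever format they want.  The effect
panel applies the log-modulus transform ``sign(x) * log1p(|x|)`` to the
display axis only — stored numbers are never transformed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers can switch backends first
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_effects", "plot_curves", "plot_surfaces", "log_modulus"]


def log_modulus(x):
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.log1p(np.abs(x))


def plot_effects(effects: pd.DataFrame) -> plt.Figure:
    """Open circles: mean over trait groups; full circles: group deviations."""
    variables = list(dict.fromkeys(effects["variable"]))
    groups = list(dict.fromkeys(effects["group"]))
    fig, axes = plt.subplots(
        len(variables), 1, figsize=(1.2 * len(groups) + 2, 1.6 * len(variables)),
        sharex=True, squeeze=False,
    )
    for ax, variable in zip(axes[:, 0], variables):
        sub = effects[effects["variable"] == variable].set_index("group")
        xs = np.arange(len(groups))
        overall = sub["overall_mean"].reindex(groups)
        ax.errorbar(
            xs - 0.15, log_modulus(overall),
            yerr=[
                log_modulus(overall) - log_modulus(sub["overall_lo"].reindex(groups)),
                log_modulus(sub["overall_hi"].reindex(groups)) - log_modulus(overall),
            ],
            fmt="o", mfc="white", color="black", label="mean over groups",
        )
        dev = sub["deviation"].reindex(groups)
        colors = ["tab:blue" if d > 0 else "tab:red" for d in dev]
        ax.scatter(xs + 0.15, log_modulus(overall + dev), c=colors, zorder=3)
        ax.axhline(0.0, lw=0.5, color="grey")
        ax.set_ylabel(variable, fontsize=8)
        ax.set_xticks(xs, groups, fontsize=8)
    fig.tight_layout()
    return fig


def plot_curves(curves: pd.DataFrame) -> plt.Figure:
    """One panel per variable; one line per trait group with 95% band."""
    variables = list(dict.fromkeys(curves["variable"]))
    fig, axes = plt.subplots(
        1, len(variables), figsize=(3.0 * len(variables), 2.6), squeeze=False
    )
    x_col = "x" if "x" in curves.columns else "x_standardized"
    for ax, variable in zip(axes[0], variables):
        sub = curves[curves["variable"] == variable]
        for group, g in sub.groupby("group"):
            ax.plot(g[x_col], g["mean"], label=group)
            ax.fill_between(g[x_col], g["lo"], g["hi"], alpha=0.15)
        ax.set_xlabel(variable, fontsize=8)
        ax.set_ylabel("recruits / ha / yr", fontsize=8)
    axes[0, -1].legend(fontsize=6)
    fig.tight_layout()
    return fig


def plot_surfaces(surfaces: pd.DataFrame) -> plt.Figure:
    """Prediction vs basal area, one line per stem-density percentile."""
    groups = list(dict.fromkeys(surfaces["group"]))
    fig, axes = plt.subplots(
        1, len(groups), figsize=(2.8 * len(groups), 2.6), squeeze=False,
        sharey=True,
    )
    for ax, group in zip(axes[0], groups):
        sub = surfaces[surfaces["group"] == group]
        for pct, g in sub.groupby("density_percentile"):
            ax.plot(g["basal_area"], g["mean"], label=f"{pct:g}th")
        ax.set_title(group, fontsize=9)
        ax.set_xlabel("basal area", fontsize=8)
    axes[0, 0].set_ylabel("recruits / ha / yr", fontsize=8)
    axes[0, -1].legend(fontsize=6, title="stem density")
    fig.tight_layout()
    return fig
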