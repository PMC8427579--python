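"""Posterior presentation layer: effect estimates, curves and surfaces.

Effect estimates are reported as the per-draw mean of the group coefficients
over trait groups (the overall effect) plus each group's deviation from that
mean, both summarized by the posterior mean and the central 95% credible
interval.  Effect curves and interaction surfaces evaluate expected recruits
per hectare and year on a covariate grid with all other standardized
covariates at 0 (their mean), random effects at 0 (the population-median
plot and species) and the offset fixed at 1 ha x 1 yr.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ingrowth.model.design import DesignMatrix
from ingrowth.model.sampler import PosteriorDraws

__all__ = ["effect_estimates", "effect_curve", "interaction_surface"]

_CI = (0.025, 0.975)


def _summary(samples: np.ndarray) -> tuple[float, float, float]:
    lo, hi = np.quantile(samples, _CI)
    return float(np.mean(samples)), float(lo), float(hi)


def effect_estimates(draws: PosteriorDraws) -> pd.DataFrame:
    """Mean-over-groups effects and per-group deviations with 95% CIs.

    One row per (variable, group); the overall columns repeat the shared
    across-group summary for convenience.
    """
    layout = draws.layout
    G, P = layout.n_groups, layout.n_cols
    beta = draws.flat()[:, layout.slices["beta"]].reshape(-1, G, P)
    group_labels = _group_labels(draws)
    col_names = _column_names(draws)
    overall = beta.mean(axis=1)  # (n_draws, P)
    deviation = beta - overall[:, None, :]
    rows = []
    for p in range(P):
        o_mean, o_lo, o_hi = _summary(overall[:, p])
        for g in range(G):
            d_mean, d_lo, d_hi = _summary(deviation[:, g, p])
            rows.append(
                {
                    "variable": col_names[p],
                    "group": group_labels[g],
                    "overall_mean": o_mean,
                    "overall_lo": o_lo,
                    "overall_hi": o_hi,
                    "deviation": d_mean,
                    "deviation_lo": d_lo,
                    "deviation_hi": d_hi,
                }
            )
    return pd.DataFrame(rows)


def _group_labels(draws: PosteriorDraws) -> list[str]:
    sl = draws.layout.slices["beta0"]
    return [
        n.removeprefix("beta0[").removesuffix("]")
        for n in draws.names[sl]
    ]


def _column_names(draws: PosteriorDraws) -> list[str]:
    G, P = draws.layout.n_groups, draws.layout.n_cols
    sl = draws.layout.slices["beta"]
    names = draws.names[sl][:P]
    return [n.split(",", 1)[1].removesuffix("]") for n in names]


def _group_rows(design: DesignMatrix, group: str) -> np.ndarray:
    g = design.group_labels.index(group)
    rows = np.flatnonzero(design.group_idx == g)
    if rows.size == 0:
        raise ValueError(f"trait group {group!r} has no observations")
    return rows


def _grid(values: np.ndarray, n_grid: int) -> np.ndarray:
    lo, hi = np.percentile(values, [1, 99])
    return np.linspace(lo, hi, n_grid)


def effect_curve(
    draws: PosteriorDraws,
    design: DesignMatrix,
    variable: str,
    group: str,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Predicted recruits/ha/yr over the group's 1st-99th covariate percentile.

    Per draw, ``mu = exp(beta0_g + beta_g_var * x)`` on the standardized grid;
    the returned frame also carries the covariate on its original scale when
    the variable is a main effect.
    """
    g = design.group_labels.index(group)
    p = design.columns.index(variable)
    rows = _group_rows(design, group)
    grid = _grid(design.X[rows, p], n_grid)
    layout = draws.layout
    beta0 = draws.flat()[:, layout.slices["beta0"]][:, g]
    beta = draws.flat()[:, layout.slices["beta"]].reshape(
        -1, layout.n_groups, layout.n_cols
    )[:, g, p]
    mu = np.exp(beta0[:, None] + beta[:, None] * grid[None, :])  # (draws, grid)
    frame = pd.DataFrame(
        {
            "variable": variable,
            "group": group,
            "x_standardized": grid,
            "mean": mu.mean(axis=0),
            "lo": np.quantile(mu, _CI[0], axis=0),
            "hi": np.quantile(mu, _CI[1], axis=0),
        }
    )
    if variable in design.scale_means:
        frame["x"] = (
            grid * design.scale_sds[variable] + design.scale_means[variable]
        )
    return frame


def interaction_surface(
    draws: PosteriorDraws,
    design: DesignMatrix,
    group: str,
    density_percentiles: Sequence[float] = (10, 30, 50, 70, 90),
    n_grid: int = 50,
) -> pd.DataFrame:
    """Prediction vs basal area at fixed stem-density percentiles.

    The linear predictor includes the basal_area x stem_density interaction,
    so curves at different density levels are non-parallel on the log scale
    whenever the interaction coefficient is non-zero.
    """
    g = design.group_labels.index(group)
    rows = _group_rows(design, group)
    p_ba = design.columns.index("basal_area")
    p_sd = design.columns.index("stem_density")
    p_int = design.columns.index("basal_area:stem_density")
    ba_grid = _grid(design.X[rows, p_ba], n_grid)
    sd_levels = np.percentile(design.X[rows, p_sd], list(density_percentiles))
    layout = draws.layout
    beta0 = draws.flat()[:, layout.slices["beta0"]][:, g]
    beta = draws.flat()[:, layout.slices["beta"]].reshape(
        -1, layout.n_groups, layout.n_cols
    )
    frames = []
    for pct, sd_val in zip(density_percentiles, sd_levels):
        eta = (
            beta0[:, None]
            + beta[:, g, p_ba][:, None] * ba_grid[None, :]
            + beta[:, g, p_sd][:, None] * sd_val
            + beta[:, g, p_int][:, None] * ba_grid[None, :] * sd_val
        )
        mu = np.exp(eta)
        frames.append(
            pd.DataFrame(
                {
                    "group": group,
                    "density_percentile": pct,
                    "basal_area_standardized": ba_grid,
                    "basal_area": ba_grid * design.scale_sds["basal_area"]
                    + design.scale_means["basal_area"],
                    "mean": mu.mean(axis=0),
                    "lo": np.quantile(mu, _CI[0], axis=0),
                    "hi": np.quantile(mu, _CI[1], axis=0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
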