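"""Shared fixtures and builders for the test suite.

All fixtures are generated programmatically; expensive artifacts (synthetic
datasets, MAP fits) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ingrowth.model.design import DesignMatrix
from ingrowth.synthdata import GeneratorConfig, make_dataset


def make_toy_design(
    n_obs: int = 20,
    n_groups: int = 2,
    n_plots: int = 4,
    n_species: int = 3,
    n_cols: int = 3,
    seed: int = 0,
    offset: float | None = None,
) -> DesignMatrix:
    """Small random design matrix for likelihood/sampler tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_obs, n_cols))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    species_idx = rng.integers(0, n_species, n_obs)
    species_group = rng.integers(0, n_groups, n_species)
    return DesignMatrix(
        y=rng.integers(0, 5, n_obs),
        X=X,
        columns=tuple(f"x{i}" for i in range(n_cols)),
        offset=(
            np.full(n_obs, offset)
            if offset is not None
            else rng.uniform(-2, 0.5, n_obs)
        ),
        plot_idx=rng.integers(0, n_plots, n_obs),
        species_idx=species_idx,
        group_idx=species_group[species_idx],
        plot_ids=tuple(f"P{i}" for i in range(n_plots)),
        species_ids=tuple(f"S{j}" for j in range(n_species)),
        group_labels=tuple(f"G{g}" for g in range(n_groups)),
        main_columns=tuple(f"x{i}" for i in range(n_cols)),
        scale_means={f"x{i}": 0.0 for i in range(n_cols)},
        scale_sds={f"x{i}": 1.0 for i in range(n_cols)},
    )


def make_daily_climate(
    plot_id: str,
    years: list[int],
    monthly_tmean: dict[int, float] | float,
    monthly_precip: dict[int, float] | float,
) -> pd.DataFrame:
    """Daily climate table with constant values within each month."""
    rows = []
    for year in years:
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        for date in dates:
            tm = (
                monthly_tmean
                if np.isscalar(monthly_tmean)
                else monthly_tmean.get(date.month, 0.0)
            )
            pr = (
                monthly_precip
                if np.isscalar(monthly_precip)
                else monthly_precip.get(date.month, 0.0)
            )
            days_in_month = date.days_in_month
            rows.append(
                {
                    "plot_id": plot_id,
                    "date": date.date().isoformat(),
                    "tmean_c": tm,
                    # spread the monthly total evenly over the days
                    "precip_mm": pr / days_in_month,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset (fast to fit)."""
    return make_dataset(GeneratorConfig(n_plots=40, n_species=8, seed=7))


@pytest.fixture(scope="session")
def small_map_draws(small_dataset):
    """MAP + Laplace fit of the small dataset, reused across tests."""
    from ingrowth.model import FitConfig, fit_posterior

    config = FitConfig(
        chains=2, iterations=400, warmup=200, retained=800, seed=11,
        method="map_laplace",
    )
    return fit_posterior(small_dataset.design, config=config)
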