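"""Acceptance-gate computations shared by the test suite and report script.

Two methodological gates are recomputed from scratch on synthetic data:

* the convergence gate -- maximum split-chain R-hat over all sampled
  parameters after fitting the default NB model with four chains;
* the collinearity gate -- maximum variance inflation factor over the six
  standardized main-effect columns of the default synthetic design.
"""

from __future__ import annotations

from ingrowth.model import FitConfig, convergence, fit_posterior, vif
from ingrowth.synthdata import GeneratorConfig, SyntheticDataset, make_dataset

__all__ = ["default_dataset", "convergence_gate", "vif_gate"]


def default_dataset(seed: int, n_plots: int = 200, n_species: int = 10) -> SyntheticDataset:
    """The default synthetic inventory: 200 plots x 10 species x 6 groups."""
    config = GeneratorConfig(
        n_plots=n_plots, n_species=n_species, n_groups=6, n_periods=1, seed=seed
    )
    return make_dataset(config)


def convergence_gate(
    seed: int,
    iterations: int = 3000,
    warmup: int = 1000,
    chains: int = 4,
) -> tuple[float, int]:
    """(max split R-hat over all sampled parameters, number of observations).

    Four HMC chains on the default synthetic dataset at reduced iteration
    counts; R-hat is computed from all post-warmup draws.
    """
    dataset = default_dataset(seed)
    config = FitConfig(
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        retained=None,
        seed=seed + 1,
        max_leapfrog=64,
        target_accept=0.85,
    )
    draws = fit_posterior(dataset.design, config=config)
    diag = convergence(draws)
    return diag.max_rhat, dataset.design.n_obs


def vif_gate(seed: int, n_plots: int = 500) -> tuple[float, int]:
    """(max VIF over the six standardized mains, number of plots)."""
    dataset = default_dataset(seed, n_plots=n_plots)
    return max(vif(dataset.design).values()), n_plots
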