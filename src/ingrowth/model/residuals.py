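"""Scaled (randomized quantile) residuals from posterior-predictive simulation.

For each observation, ``n_sim`` counts are simulated from randomly selected
posterior draws (fitted random effects included) and the observed count's
randomized rank among them is returned.  Under a correctly specified model
the residuals are uniform on [0, 1].
"""

from __future__ import annotations

import numpy as np

from ingrowth.model.design import DesignMatrix
from ingrowth.model.families import Family, get_family
from ingrowth.model.sampler import PosteriorDraws

__all__ = ["scaled_residuals", "simulate_predictive"]


def simulate_predictive(
    draws: PosteriorDraws,
    design: DesignMatrix,
    n_sim: int,
    family: str | Family = "nb",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """(n_sim, n_obs) posterior-predictive count simulations."""
    rng = rng or np.random.default_rng(0)
    fam = get_family(family)
    flat = draws.flat()
    sims = np.empty((n_sim, design.n_obs), dtype=int)
    draw_idx = rng.integers(0, flat.shape[0], size=n_sim)
    for s in range(n_sim):
        vec = flat[draw_idx[s]]
        params = draws.layout.to_params(vec)
        # Clip so simulators cannot overflow on wide approximate-posterior draws.
        mu = np.exp(np.clip(params.linear_predictor(design), -30, 30))
        extras = draws.layout.extras(vec)
        sims[s] = fam.simulate(rng, mu, extras)
    return sims


def scaled_residuals(
    draws: PosteriorDraws,
    design: DesignMatrix,
    n_sim: int = 250,
    family: str | Family = "nb",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Randomized PIT residuals in [0, 1], one per observation.

    ``r = (#{sim < y} + U * (#{sim == y} + 1)) / (n_sim + 1)`` with
    ``U ~ Uniform(0, 1)``; discrete ties are randomized so the statistic is
    exactly uniform under the predictive distribution.
    """
    if n_sim < 20:
        raise ValueError("n_sim must be >= 20 for stable residuals")
    rng = rng or np.random.default_rng(0)
    sims = simulate_predictive(draws, design, n_sim, family, rng)
    y = design.y
    below = (sims < y[None, :]).sum(axis=0)
    equal = (sims == y[None, :]).sum(axis=0)
    u = rng.random(design.n_obs)
    return (below + u * (equal + 1)) / (n_sim + 1)
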