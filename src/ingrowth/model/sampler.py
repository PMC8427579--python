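"""Posterior fitting: adaptive Hamiltonian Monte Carlo and MAP + Laplace.

The default sampler is an in-repo HMC with dual-averaged step size and
diagonal mass-matrix adaptation during warmup (non-centered parameterization,
analytic gradients).  A fast ``map_laplace`` mode optimizes the same density
with L-BFGS and draws from the Gaussian (Laplace) approximation at the mode;
it is intended for tests, family comparison and replicate experiments.

Both modes are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import optimize

from ingrowth.model.design import DesignMatrix
from ingrowth.model.families import Family, get_family
from ingrowth.model.params import (
    ModelParameters,
    ParameterLayout,
    PosteriorDensity,
    Priors,
)

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "PosteriorDraws", "fit_posterior", "map_estimate"]


@dataclasses.dataclass(frozen=True)
class FitConfig:
    """Sampler configuration.

    Defaults mirror the reference setup (4 chains x 5,000 iterations with a
    2,000-iteration warmup, 3,000 retained draws); reduce ``iterations`` for
    desk-scale runs and the retained count scales with them.
    """

    chains: int = 4
    iterations: int = 5000  # per chain, including warmup
    warmup: int = 2000
    retained: int | None = 3000  # total post-warmup draws kept across chains
    seed: int = 0
    method: str = "hmc"  # "hmc" or "map_laplace"
    target_accept: float = 0.8
    max_leapfrog: int = 48
    jitter: float = 0.1

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations <= self.warmup or self.warmup < 0:
            raise ValueError("need chains >= 1 and iterations > warmup >= 0")
        if self.method not in ("hmc", "map_laplace"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def post_warmup(self) -> int:
        return self.iterations - self.warmup


@dataclasses.dataclass
class PosteriorDraws:
    """Retained posterior draws, indexed chain x iteration x parameter."""

    draws: np.ndarray  # (chains, n_kept, n_params) unconstrained vectors
    layout: ParameterLayout
    config: FitConfig
    accept_rate: float = float("nan")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def names(self) -> list[str]:
        return self.layout.names

    def flat(self) -> np.ndarray:
        """(n_total, n_params) draws pooled across chains."""
        return self.draws.reshape(-1, self.draws.shape[2])

    def parameters(self, chain: int, iteration: int) -> ModelParameters:
        return self.layout.to_params(self.draws[chain, iteration])

    def iter_parameters(self) -> Iterator[ModelParameters]:
        for vec in self.flat():
            yield self.layout.to_params(vec)

    def group_coefficients(self, design: DesignMatrix) -> np.ndarray:
        """(n_total, G, P) natural-scale group coefficients."""
        G, P = self.layout.n_groups, self.layout.n_cols
        sl = self.layout.slices["beta"]
        return self.flat()[:, sl].reshape(-1, G, P)

    def intercepts(self) -> np.ndarray:
        """(n_total, G) group intercepts."""
        return self.flat()[:, self.layout.slices["beta0"]]

    def to_frame(self) -> pd.DataFrame:
        """One row per chain x iteration, one column per parameter."""
        flat = self.flat()
        frame = pd.DataFrame(flat, columns=self.names)
        n_kept = self.draws.shape[1]
        frame.insert(0, "chain", np.repeat(np.arange(self.n_chains), n_kept))
        frame.insert(1, "iteration", np.tile(np.arange(n_kept), self.n_chains))
        return frame


def fit_posterior(
    design: DesignMatrix,
    family: str | Family = "nb",
    config: FitConfig | None = None,
    priors: Priors | None = None,
) -> PosteriorDraws:
    """Fit the hierarchical count model and return retained draws."""
    config = config or FitConfig()
    fam = get_family(family)
    density = PosteriorDensity(design, priors, fam)
    if config.method == "map_laplace":
        return _fit_map_laplace(density, config)
    return _fit_hmc(density, config)


# ---------------------------------------------------------------------------
# HMC


def _fit_hmc(density: PosteriorDensity, config: FitConfig) -> PosteriorDraws:
    seeds = np.random.SeedSequence(config.seed).spawn(config.chains)
    chains = []
    accepts = []
    for c in range(config.chains):
        rng = np.random.default_rng(seeds[c])
        kept, acc = _run_chain(density, config, rng)
        chains.append(kept)
        accepts.append(acc)
    draws = np.stack(chains)  # (chains, post_warmup, n_params)
    draws = _thin(draws, config)
    return PosteriorDraws(
        draws=draws,
        layout=density.layout,
        config=config,
        accept_rate=float(np.mean(accepts)),
    )


def _thin(draws: np.ndarray, config: FitConfig) -> np.ndarray:
    if config.retained is None:
        return draws
    per_chain = max(1, config.retained // draws.shape[0])
    n = draws.shape[1]
    if per_chain >= n:
        return draws
    idx = np.unique(np.linspace(0, n - 1, per_chain).round().astype(int))
    return draws[:, idx, :]


def _run_chain(
    density: PosteriorDensity, config: FitConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    n_params = density.layout.n_params
    theta = density.layout.initial_vector(rng, config.jitter)
    logp, grad = density.logp_grad(theta)
    if not np.isfinite(logp):
        raise RuntimeError(
            "non-finite posterior at the initial state; check the design for "
            "extreme offsets or counts"
        )

    inv_mass = np.ones(n_params)
    step = _find_initial_step(density, theta, logp, grad, inv_mass, rng)
    dual = _DualAveraging(step, config.target_accept)

    # Warmup schedule: a step-size-only initial buffer, expanding
    # variance-estimation windows (mass matrix updated at each window end),
    # and a step-size-only terminal buffer.
    w = config.warmup
    init_buf = min(max(1, int(0.15 * w)), 75)
    term_buf = min(max(1, int(0.15 * w)), 150)
    window_ends = _adaptation_windows(init_buf, w - term_buf)
    welford = _Welford(n_params)

    kept = np.empty((config.post_warmup, n_params))
    n_accept = 0
    n_total = 0
    for it in range(config.iterations):
        warming = it < w
        lo = max(1, config.max_leapfrog // 2)
        n_leap = int(rng.integers(lo, config.max_leapfrog + 1))
        theta, logp, grad, alpha = _hmc_step(
            density, theta, logp, grad, step, n_leap, inv_mass, rng
        )
        if warming:
            step = dual.update(alpha)
            if init_buf <= it < w - term_buf:
                welford.add(theta)
            if it in window_ends and welford.count > 10:
                inv_mass = np.clip(welford.variance(), 1e-6, 1e6)
                welford = _Welford(n_params)
                step = _find_initial_step(
                    density, theta, logp, grad, inv_mass, rng
                )
                dual = _DualAveraging(step, config.target_accept)
                logger.info(
                    "warmup %d: mass window closed, step reset to %.3g "
                    "(inv_mass median %.3g)",
                    it + 1, step, float(np.median(inv_mass)),
                )
            if it == w - 1:
                step = dual.adapted()
                logger.info("warmup done: sampling step size %.3g", step)
        else:
            kept[it - w] = theta
            n_accept += alpha
            n_total += 1
    return kept, n_accept / max(n_total, 1)


def _adaptation_windows(start: int, end: int, first: int = 25) -> set[int]:
    """Iteration indices ending each expanding (doubling) adaptation window."""
    ends: set[int] = set()
    pos, width = start, first
    while pos + width < end:
        pos += width
        ends.add(pos - 1)
        width *= 2
    ends.add(end - 1)
    return ends


def _hmc_step(density, theta, logp, grad, step, n_leap, inv_mass, rng):
    momentum = rng.normal(size=theta.size) / np.sqrt(inv_mass)
    h0 = logp - 0.5 * float(np.sum(momentum**2 * inv_mass))
    q, g = theta.copy(), grad.copy()
    p = momentum + 0.5 * step * g
    lp = logp
    for i in range(n_leap):
        q = q + step * inv_mass * p
        lp, g = density.logp_grad(q)
        if not np.isfinite(lp):
            return theta, logp, grad, 0.0
        p = p + (step if i < n_leap - 1 else 0.5 * step) * g
    h1 = lp - 0.5 * float(np.sum(p**2 * inv_mass))
    log_alpha = min(0.0, h1 - h0)
    alpha = float(np.exp(log_alpha))
    if np.log(rng.random()) < log_alpha:
        return q, lp, g, alpha
    return theta, logp, grad, alpha


def _find_initial_step(density, theta, logp, grad, inv_mass, rng, step=0.1):
    """Double/halve the step until one-leapfrog acceptance crosses 0.5."""
    direction = None
    for _ in range(50):
        _, _, _, alpha = _hmc_step(density, theta, logp, grad, step, 1, inv_mass, rng)
        if direction is None:
            direction = 1 if alpha > 0.5 else -1
        if direction == 1 and alpha <= 0.5:
            break
        if direction == -1 and alpha > 0.5:
            break
        step *= 2.0 if direction == 1 else 0.5
    return step


class _DualAveraging:
    """Nesterov dual averaging of log step size (Hoffman & Gelman 2014)."""

    def __init__(self, step0: float, target: float):
        self.mu = np.log(10.0 * step0)
        self.target = target
        self.log_step = np.log(step0)
        self.log_step_bar = 0.0
        self.h_bar = 0.0
        self.t = 0
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75

    def update(self, alpha: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - alpha)
        self.log_step = self.mu - np.sqrt(self.t) / self.gamma * self.h_bar
        eta = self.t**-self.kappa
        self.log_step_bar = eta * self.log_step + (1 - eta) * self.log_step_bar
        return float(np.exp(self.log_step))

    def adapted(self) -> float:
        return float(np.exp(self.log_step_bar))


class _Welford:
    def __init__(self, n: int):
        self.count = 0
        self.mean = np.zeros(n)
        self.m2 = np.zeros(n)

    def add(self, x: np.ndarray) -> None:
        self.count += 1
        delta = x - self.mean
        self.mean += delta / self.count
        self.m2 += delta * (x - self.mean)

    def variance(self) -> np.ndarray:
        return self.m2 / max(self.count - 1, 1)


# ---------------------------------------------------------------------------
# MAP + Laplace


def map_estimate(
    density: PosteriorDensity, seed: int = 0, maxiter: int = 2000
) -> tuple[np.ndarray, float]:
    """Posterior mode of the unconstrained density via L-BFGS."""
    rng = np.random.default_rng(seed)
    theta0 = density.layout.initial_vector(rng, jitter=0.01)

    def objective(theta):
        lp, grad = density.logp_grad(theta)
        if not np.isfinite(lp):
            return 1e12, np.zeros_like(theta)
        return -lp, -grad

    res = optimize.minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "maxfun": 5 * maxiter},
    )
    if not res.success and "ROUNDING" not in str(res.message).upper():
        logger.warning("MAP optimization did not fully converge: %s", res.message)
    return res.x, -float(res.fun)


def _laplace_covariance(density: PosteriorDensity, mode: np.ndarray) -> np.ndarray:
    """Inverse negative Hessian, from central differences of the gradient."""
    n = mode.size
    eps = 1e-4 * np.maximum(1.0, np.abs(mode))
    hess = np.empty((n, n))
    for i in range(n):
        up, down = mode.copy(), mode.copy()
        up[i] += eps[i]
        down[i] -= eps[i]
        _, g_up = density.logp_grad(up)
        _, g_down = density.logp_grad(down)
        hess[i] = (g_up - g_down) / (2.0 * eps[i])
    hess = 0.5 * (hess + hess.T)
    neg_hess = -hess
    # Clamp the spectrum so near-flat directions get a wide, finite variance.
    vals, vecs = np.linalg.eigh(neg_hess)
    vals = np.clip(vals, 1e-8, None)
    return (vecs / vals) @ vecs.T


def _fit_map_laplace(density: PosteriorDensity, config: FitConfig) -> PosteriorDraws:
    mode, _ = map_estimate(density, seed=config.seed)
    cov = _laplace_covariance(density, mode)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
    total = config.retained or config.chains * config.post_warmup
    per_chain = max(1, total // config.chains)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    noise = rng.normal(size=(config.chains, per_chain, mode.size))
    draws = mode[None, None, :] + noise @ chol.T
    return PosteriorDraws(
        draws=draws, layout=density.layout, config=config, accept_rate=1.0
    )
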