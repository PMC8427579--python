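"""Model parameters, priors, and the hierarchical log posterior.

The linear predictor for row ``(i, t, j)`` with trait group ``g`` is::

    log mu = offset + beta0[g] + u0_plot[i] + u0_species[j]
             + sum_m (beta[g, m] + u_species[j, m]) * x[, m]

with normal random effects and an NB2 likelihood by default.

Two parameterizations coexist:

* the *natural* (centered) one, :class:`ModelParameters`, used by the public
  :func:`log_posterior` and by everything downstream of fitting;
* an *unconstrained, non-centered* vector used internally by the sampler and
  optimizer (``u = sigma * z``, ``log sigma``, family extras on log/logit
  scales), which avoids the hierarchical funnel and makes every coordinate
  free.  :class:`ParameterLayout` converts between the two.
"""

from __future__ import annotations

import dataclasses
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import digamma, gammaln

from ingrowth.model.families import Family, NegativeBinomial, get_family

if TYPE_CHECKING:  # pragma: no cover
    from ingrowth.model.design import DesignMatrix

__all__ = ["Priors", "ModelParameters", "ParameterLayout", "log_posterior"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclasses.dataclass(frozen=True)
class Priors:
    """Weakly informative defaults; all scales configurable."""

    beta_sd: float = 5.0  # normal(0, beta_sd) on intercepts and coefficients
    sigma_scale: float = 2.0  # half-normal(0, sigma_scale) on random-effect sds
    # The dispersion prior (gamma on phi) lives with the family extras.


@dataclasses.dataclass
class ModelParameters:
    """Natural-scale parameters of the recruitment model."""

    beta0: np.ndarray  # (G,)
    beta: np.ndarray  # (G, P)
    u0_plot: np.ndarray  # (I,)
    u0_species: np.ndarray  # (J,)
    u_species: np.ndarray  # (J, P)
    sigma_plot: float
    sigma_species: float
    sigma_slopes: np.ndarray  # (P,) one scale per variable
    phi: float  # NB dispersion; ignored by phi-free families

    def __post_init__(self) -> None:
        self.beta0 = np.atleast_1d(np.asarray(self.beta0, dtype=float))
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.u0_plot = np.atleast_1d(np.asarray(self.u0_plot, dtype=float))
        self.u0_species = np.atleast_1d(np.asarray(self.u0_species, dtype=float))
        self.u_species = np.atleast_2d(np.asarray(self.u_species, dtype=float))
        self.sigma_slopes = np.atleast_1d(np.asarray(self.sigma_slopes, dtype=float))
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if self.sigma_plot <= 0 or self.sigma_species <= 0:
            raise ValueError("random-effect scales must be > 0")
        if np.any(self.sigma_slopes <= 0):
            raise ValueError("random-effect scales must be > 0")

    @classmethod
    def zeros(
        cls,
        n_groups: int,
        n_cols: int,
        n_plots: int,
        n_species: int,
        sigma: float = 1.0,
        phi: float = 1.0,
    ) -> "ModelParameters":
        return cls(
            beta0=np.zeros(n_groups),
            beta=np.zeros((n_groups, n_cols)),
            u0_plot=np.zeros(n_plots),
            u0_species=np.zeros(n_species),
            u_species=np.zeros((n_species, n_cols)),
            sigma_plot=sigma,
            sigma_species=sigma,
            sigma_slopes=np.full(n_cols, sigma),
            phi=phi,
        )

    def linear_predictor(self, design: "DesignMatrix") -> np.ndarray:
        eta = (
            design.offset
            + self.beta0[design.group_idx]
            + self.u0_plot[design.plot_idx]
            + self.u0_species[design.species_idx]
            + np.sum(self.beta[design.group_idx, :] * design.X, axis=1)
            + np.sum(self.u_species[design.species_idx, :] * design.X, axis=1)
        )
        return eta


def _normal_logpdf_sum(x: np.ndarray, sd: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(-0.5 * np.sum(x**2) / sd**2 - x.size * (np.log(sd) + 0.5 * _LOG_2PI))


def _half_normal_logpdf(x: float, scale: float) -> float:
    return float(
        np.log(2.0) - 0.5 * _LOG_2PI - np.log(scale) - 0.5 * (x / scale) ** 2
    )


def log_posterior(
    params: ModelParameters,
    design: "DesignMatrix",
    priors: Priors | None = None,
    family: str | Family = "nb",
) -> float:
    """Unnormalized log posterior density at natural-scale parameters.

    Sum of the per-observation family log pmf at ``mu = exp(eta)``, the
    normal log densities of all random effects, and the prior log densities
    of coefficients, random-effect scales and dispersion.  Returns ``-inf``
    for non-finite linear predictors.
    """
    priors = priors or Priors()
    fam = get_family(family)
    eta = params.linear_predictor(design)
    if not np.all(np.isfinite(eta)):
        return -np.inf
    mu = np.exp(eta)
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        return -np.inf
    extras = _extras_from_params(fam, params)
    lp = float(np.sum(fam.log_pmf(design.y, mu, extras)))
    lp += _normal_logpdf_sum(params.u0_plot, params.sigma_plot)
    lp += _normal_logpdf_sum(params.u0_species, params.sigma_species)
    for p in range(params.u_species.shape[1]):
        lp += _normal_logpdf_sum(params.u_species[:, p], float(params.sigma_slopes[p]))
    lp += _normal_logpdf_sum(params.beta0, priors.beta_sd)
    lp += _normal_logpdf_sum(params.beta, priors.beta_sd)
    lp += _half_normal_logpdf(params.sigma_plot, priors.sigma_scale)
    lp += _half_normal_logpdf(params.sigma_species, priors.sigma_scale)
    for s in params.sigma_slopes:
        lp += _half_normal_logpdf(float(s), priors.sigma_scale)
    # Extras prior without the unconstrained-scale Jacobian: the natural-scale
    # gamma density on phi.
    if isinstance(fam, NegativeBinomial) or "log_phi" in fam.extra_names:
        idx = fam.extra_names.index("log_phi")
        lp += fam.extras_log_prior(extras) - extras[idx]
    else:
        lp += fam.extras_log_prior(extras)
    return lp


def _extras_from_params(fam: Family, params: ModelParameters) -> np.ndarray:
    extras = fam.default_extras()
    for i, name in enumerate(fam.extra_names):
        if name == "log_phi":
            extras[i] = np.log(params.phi)
    return extras


class ParameterLayout:
    """Index bookkeeping for the unconstrained non-centered vector.

    Order: beta0 (G), beta (G*P row-major), z_plot (I), z_species (J),
    z_slopes (J*P row-major), log_sigma_plot, log_sigma_species,
    log_sigma_slopes (P), family extras.
    """

    def __init__(self, design: "DesignMatrix", family: str | Family = "nb"):
        self.family = get_family(family)
        self.n_groups = design.n_groups
        self.n_cols = design.n_cols
        self.n_plots = design.n_plots
        self.n_species = design.n_species
        G, P, I, J = self.n_groups, self.n_cols, self.n_plots, self.n_species
        sizes = {
            "beta0": G,
            "beta": G * P,
            "z_plot": I,
            "z_species": J,
            "z_slopes": J * P,
            "log_sigma_plot": 1,
            "log_sigma_species": 1,
            "log_sigma_slopes": P,
            "extras": self.family.n_extra,
        }
        self.slices: dict[str, slice] = {}
        start = 0
        for name, size in sizes.items():
            self.slices[name] = slice(start, start + size)
            start += size
        self.n_params = start
        self._names = self._build_names(design)

    def _build_names(self, design: "DesignMatrix") -> list[str]:
        names: list[str] = []
        names += [f"beta0[{g}]" for g in design.group_labels]
        names += [
            f"beta[{g},{c}]" for g in design.group_labels for c in design.columns
        ]
        names += [f"z_plot[{p}]" for p in design.plot_ids]
        names += [f"z_species[{s}]" for s in design.species_ids]
        names += [
            f"z_slope[{s},{c}]" for s in design.species_ids for c in design.columns
        ]
        names += ["log_sigma_plot", "log_sigma_species"]
        names += [f"log_sigma_slope[{c}]" for c in design.columns]
        names += list(self.family.extra_names)
        return names

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def initial_vector(self, rng: np.random.Generator, jitter: float = 0.1):
        theta = rng.normal(0.0, jitter, size=self.n_params)
        theta[self.slices["log_sigma_plot"]] = np.log(0.5) + rng.normal(0, jitter)
        theta[self.slices["log_sigma_species"]] = np.log(0.5) + rng.normal(0, jitter)
        theta[self.slices["log_sigma_slopes"]] = np.log(0.5) + rng.normal(
            0, jitter, self.n_cols
        )
        theta[self.slices["extras"]] = self.family.default_extras() + rng.normal(
            0, jitter, self.family.n_extra
        )
        return theta

    def to_params(self, theta: np.ndarray) -> ModelParameters:
        """Natural-scale view of an unconstrained vector (u = sigma * z)."""
        G, P, I, J = self.n_groups, self.n_cols, self.n_plots, self.n_species
        s = self.slices
        sigma_plot = float(np.exp(theta[s["log_sigma_plot"]])[0])
        sigma_species = float(np.exp(theta[s["log_sigma_species"]])[0])
        sigma_slopes = np.exp(theta[s["log_sigma_slopes"]])
        extras = theta[s["extras"]]
        phi = 1.0
        if "log_phi" in self.family.extra_names:
            phi = float(np.exp(extras[self.family.extra_names.index("log_phi")]))
        return ModelParameters(
            beta0=theta[s["beta0"]].copy(),
            beta=theta[s["beta"]].reshape(G, P).copy(),
            u0_plot=sigma_plot * theta[s["z_plot"]],
            u0_species=sigma_species * theta[s["z_species"]],
            u_species=theta[s["z_slopes"]].reshape(J, P) * sigma_slopes[None, :],
            sigma_plot=sigma_plot,
            sigma_species=sigma_species,
            sigma_slopes=sigma_slopes.copy(),
            phi=phi,
        )

    def extras(self, theta: np.ndarray) -> np.ndarray:
        return theta[self.slices["extras"]]


class PosteriorDensity:
    """Callable unconstrained log density with analytic gradient.

    Evaluates the same posterior as :func:`log_posterior` after the
    non-centered change of variables (z, log sigma, extras), including all
    Jacobian terms, so MCMC on this density targets the model posterior.
    """

    def __init__(
        self,
        design: "DesignMatrix",
        priors: Priors | None = None,
        family: str | Family = "nb",
    ):
        from ingrowth.model.design import DesignMatrix  # noqa: F401 (typing aid)

        self.design = design
        self.priors = priors or Priors()
        self.family = get_family(family)
        self.layout = ParameterLayout(design, self.family)
        # Per-group and per-species row indices, precomputed for gradients.
        self._group_rows = [
            np.flatnonzero(design.group_idx == g) for g in range(design.n_groups)
        ]
        # Fast path for the default NB family: cache count-only terms.
        self._nb_fast = isinstance(self.family, NegativeBinomial)
        if self._nb_fast:
            self._y_float = design.y.astype(float)
            self._lgamma_y1 = gammaln(self._y_float + 1.0)

    def __call__(self, theta: np.ndarray) -> float:
        return self.logp_grad(theta)[0]

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.design
        lay = self.layout
        s = lay.slices
        fam = self.family
        G, P, I, J = lay.n_groups, lay.n_cols, lay.n_plots, lay.n_species

        beta0 = theta[s["beta0"]]
        beta = theta[s["beta"]].reshape(G, P)
        z_plot = theta[s["z_plot"]]
        z_species = theta[s["z_species"]]
        z_slopes = theta[s["z_slopes"]].reshape(J, P)
        log_sigma_plot = theta[s["log_sigma_plot"]][0]
        log_sigma_species = theta[s["log_sigma_species"]][0]
        log_sigma_slopes = theta[s["log_sigma_slopes"]]
        extras = theta[s["extras"]]

        # Reject runaway scale states before exponentiating.
        if (
            abs(log_sigma_plot) > 30
            or abs(log_sigma_species) > 30
            or np.any(np.abs(log_sigma_slopes) > 30)
            or np.any(np.abs(extras) > 30)
        ):
            return -np.inf, np.zeros(lay.n_params)

        sigma_plot = np.exp(log_sigma_plot)
        sigma_species = np.exp(log_sigma_species)
        sigma_slopes = np.exp(log_sigma_slopes)

        u0_plot = sigma_plot * z_plot
        u0_species = sigma_species * z_species
        u_slopes = z_slopes * sigma_slopes[None, :]

        eta = (
            d.offset
            + beta0[d.group_idx]
            + u0_plot[d.plot_idx]
            + u0_species[d.species_idx]
            + np.sum(beta[d.group_idx, :] * d.X, axis=1)
            + np.sum(u_slopes[d.species_idx, :] * d.X, axis=1)
        )
        # Reject numerically wild states (exp under/overflow) outright.
        if np.any(np.abs(eta) > 50) or np.any(np.abs(extras) > 30):
            return -np.inf, np.zeros(lay.n_params)
        mu = np.exp(eta)

        if self._nb_fast:
            logp, r, dlog_dlogphi = self._nb_terms(mu, extras)
        else:
            logp = float(np.sum(fam.log_pmf(d.y, mu, extras)))
            r = fam.dlog_deta(d.y, mu, extras)  # (n,)
            dlog_dlogphi = None

        grad = np.zeros(lay.n_params)

        # Fixed effects.
        g_beta0 = np.bincount(d.group_idx, weights=r, minlength=G)
        g_beta = np.empty((G, P))
        for g, rows in enumerate(self._group_rows):
            g_beta[g] = d.X[rows].T @ r[rows]
        grad[s["beta0"]] = g_beta0 - beta0 / self.priors.beta_sd**2
        grad[s["beta"]] = (g_beta - beta / self.priors.beta_sd**2).ravel()
        logp += _normal_logpdf_sum(beta0, self.priors.beta_sd)
        logp += _normal_logpdf_sum(beta, self.priors.beta_sd)

        # Plot intercepts (non-centered).
        du_plot = np.bincount(d.plot_idx, weights=r, minlength=I)  # dlogp/du0_plot
        grad[s["z_plot"]] = sigma_plot * du_plot - z_plot
        logp += _normal_logpdf_sum(z_plot, 1.0)

        # Species intercepts.
        du_species = np.bincount(d.species_idx, weights=r, minlength=J)
        grad[s["z_species"]] = sigma_species * du_species - z_species
        logp += _normal_logpdf_sum(z_species, 1.0)

        # Species random slopes.
        du_slopes = np.empty((J, P))  # dlogp/du_species[j, p]
        for p in range(P):
            du_slopes[:, p] = np.bincount(
                d.species_idx, weights=r * d.X[:, p], minlength=J
            )
        grad[s["z_slopes"]] = (du_slopes * sigma_slopes[None, :] - z_slopes).ravel()
        logp += _normal_logpdf_sum(z_slopes, 1.0)

        # Random-effect scales: half-normal prior + log Jacobian, plus the
        # likelihood path through u = sigma * z.
        tau = self.priors.sigma_scale
        grad[s["log_sigma_plot"]] = (
            sigma_plot * float(du_plot @ z_plot) - sigma_plot**2 / tau**2 + 1.0
        )
        grad[s["log_sigma_species"]] = (
            sigma_species * float(du_species @ z_species)
            - sigma_species**2 / tau**2
            + 1.0
        )
        grad[s["log_sigma_slopes"]] = (
            sigma_slopes * np.sum(du_slopes * z_slopes, axis=0)
            - sigma_slopes**2 / tau**2
            + 1.0
        )
        for val, lsig in (
            (sigma_plot, log_sigma_plot),
            (sigma_species, log_sigma_species),
        ):
            logp += _half_normal_logpdf(float(val), tau) + float(lsig)
        logp += float(
            np.sum(
                [
                    _half_normal_logpdf(float(sv), tau) + float(lv)
                    for sv, lv in zip(sigma_slopes, log_sigma_slopes)
                ]
            )
        )

        # Family extras (dispersion, mixture weights).
        if fam.n_extra:
            if dlog_dlogphi is not None:
                grad[s["extras"]] = dlog_dlogphi + fam.extras_log_prior_grad(extras)
            else:
                grad[s["extras"]] = np.sum(
                    fam.dlog_dextras(d.y, mu, extras), axis=0
                ) + fam.extras_log_prior_grad(extras)
            logp += fam.extras_log_prior(extras)

        if not np.isfinite(logp):
            return -np.inf, np.zeros(lay.n_params)
        return logp, grad

    def _nb_terms(self, mu, extras):
        """NB2 log likelihood, d/deta and d/dlog phi with shared subexpressions."""
        y = self._y_float
        phi = float(np.exp(extras[0]))
        mu_phi = mu + phi
        log_mu_phi = np.log(mu_phi)
        y_phi = y + phi
        lg_y_phi = gammaln(y_phi)
        ll = (
            lg_y_phi
            - gammaln(phi)
            - self._lgamma_y1
            + phi * (np.log(phi) - log_mu_phi)
            + y * (np.log(mu) - log_mu_phi)
        )
        r = y - mu * y_phi / mu_phi
        dphi = (
            digamma(y_phi)
            - digamma(phi)
            + (np.log(phi) - log_mu_phi)
            + 1.0
            - y_phi / mu_phi
        )
        return float(ll.sum()), r, np.array([float(dphi.sum()) * phi])
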