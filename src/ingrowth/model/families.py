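"""Count-data families on the log-mean scale.

Each family exposes the log pmf, its derivatives with respect to the linear
predictor eta = log(mu) and any extra (unconstrained) parameters, log priors
for the extras, and a simulator.  The default family is the NB2 negative
binomial with variance mu + mu^2/phi, whose zero probability is
``(phi/(mu+phi))^phi``.

Extra parameters are carried on unconstrained scales (log phi, logit pi) so
samplers and optimizers can treat the parameter vector as free.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, expit, gammaln

__all__ = [
    "Family",
    "Poisson",
    "NegativeBinomial",
    "ZeroInflatedPoisson",
    "ZeroInflatedNegativeBinomial",
    "HurdleNegativeBinomial",
    "FAMILIES",
    "get_family",
    "nb_log_pmf",
    "poisson_log_pmf",
]

# Gamma(shape, rate) prior on phi; Beta-like (flat) prior on mixture weights.
_PHI_PRIOR_SHAPE = 2.0
_PHI_PRIOR_RATE = 0.1


def _check_counts(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if np.any(yf != np.floor(yf)):
            raise ValueError("counts must be integers")
        y = yf.astype(int)
    if np.any(y < 0):
        raise ValueError("counts must be >= 0")
    return y


def poisson_log_pmf(y, mu) -> np.ndarray:
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    return y * np.log(mu) - mu - gammaln(y + 1.0)


def nb_log_pmf(y, mu, phi) -> np.ndarray:
    """NB2 log pmf with mean ``mu`` and dispersion ``phi`` (variance mu + mu^2/phi)."""
    y = _check_counts(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0) or phi <= 0:
        raise ValueError("mu and phi must be > 0")
    return (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1.0)
        + phi * (np.log(phi) - np.log(mu + phi))
        + y * (np.log(mu) - np.log(mu + phi))
    )


def _nb_dlog_deta(y, mu, phi):
    return y - mu * (y + phi) / (mu + phi)


def _nb_dlog_dphi(y, mu, phi):
    return (
        digamma(y + phi)
        - digamma(phi)
        + np.log(phi / (mu + phi))
        + 1.0
        - (y + phi) / (mu + phi)
    )


def _nb_p0(mu, phi):
    return np.exp(phi * (np.log(phi) - np.log(mu + phi)))


class Family:
    """Interface for count families; subclasses fill in the math."""

    name: str = ""
    extra_names: tuple[str, ...] = ()  # unconstrained extra parameter names

    @property
    def n_extra(self) -> int:
        return len(self.extra_names)

    def default_extras(self) -> np.ndarray:
        return np.zeros(self.n_extra)

    def log_pmf(self, y, mu, extras: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dlog_deta(self, y, mu, extras: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def dlog_dextras(self, y, mu, extras: np.ndarray) -> np.ndarray:
        """(n_obs, n_extra) derivative matrix; empty for extras-free families."""
        return np.zeros((np.size(y), 0))

    def extras_log_prior(self, extras: np.ndarray) -> float:
        return 0.0

    def extras_log_prior_grad(self, extras: np.ndarray) -> np.ndarray:
        return np.zeros(self.n_extra)

    def simulate(self, rng: np.random.Generator, mu, extras: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover
        return f"<{type(self).__name__}>"


class Poisson(Family):
    name = "poisson"

    def log_pmf(self, y, mu, extras):
        return poisson_log_pmf(y, mu)

    def dlog_deta(self, y, mu, extras):
        return np.asarray(y, dtype=float) - mu

    def simulate(self, rng, mu, extras):
        return rng.poisson(mu)


class NegativeBinomial(Family):
    name = "nb"
    extra_names = ("log_phi",)

    def log_pmf(self, y, mu, extras):
        return nb_log_pmf(y, mu, np.exp(extras[0]))

    def dlog_deta(self, y, mu, extras):
        return _nb_dlog_deta(y, mu, np.exp(extras[0]))

    def dlog_dextras(self, y, mu, extras):
        phi = np.exp(extras[0])
        return (_nb_dlog_dphi(y, mu, phi) * phi)[:, None]  # chain rule to log phi

    def extras_log_prior(self, extras):
        phi = np.exp(extras[0])
        # Gamma(shape, rate) density plus the log-phi Jacobian.
        return (
            _PHI_PRIOR_SHAPE * np.log(_PHI_PRIOR_RATE)
            - gammaln(_PHI_PRIOR_SHAPE)
            + (_PHI_PRIOR_SHAPE - 1.0) * np.log(phi)
            - _PHI_PRIOR_RATE * phi
            + extras[0]
        )

    def extras_log_prior_grad(self, extras):
        phi = np.exp(extras[0])
        return np.array([_PHI_PRIOR_SHAPE - _PHI_PRIOR_RATE * phi])

    def simulate(self, rng, mu, extras):
        phi = np.exp(extras[0])
        # Gamma-Poisson mixture: lambda ~ Gamma(phi, scale=mu/phi), y ~ Pois(lambda).
        lam = rng.gamma(shape=phi, scale=np.asarray(mu) / phi)
        return rng.poisson(lam)


class _ZeroInflatedMixin:
    """Shared zero-inflation algebra: P(y) = pi*1{y=0} + (1-pi)*base(y)."""

    def _mix(self, y, mu, base_log_pmf, extras_logit_pi):
        pi = expit(extras_logit_pi)
        out = np.where(
            np.asarray(y) == 0,
            np.log(pi + (1.0 - pi) * np.exp(base_log_pmf) + 1e-300),
            np.log1p(-pi) + base_log_pmf,
        )
        return out


class ZeroInflatedPoisson(_ZeroInflatedMixin, Family):
    name = "zi-poisson"
    extra_names = ("logit_pi",)

    def default_extras(self):
        return np.array([-1.0])  # pi ~ 0.27 start

    def log_pmf(self, y, mu, extras):
        return self._mix(y, mu, poisson_log_pmf(y, mu), extras[0])

    def dlog_deta(self, y, mu, extras):
        y = np.asarray(y, dtype=float)
        pi = expit(extras[0])
        p0 = np.exp(-mu)
        denom = pi + (1.0 - pi) * p0
        zero_case = -(1.0 - pi) * p0 * mu / denom
        return np.where(y == 0, zero_case, y - mu)

    def dlog_dextras(self, y, mu, extras):
        y = np.asarray(y, dtype=float)
        pi = expit(extras[0])
        dpi = pi * (1.0 - pi)  # d pi / d logit pi
        p0 = np.exp(-mu)
        denom = pi + (1.0 - pi) * p0
        grad = np.where(y == 0, (1.0 - p0) * dpi / denom, -pi)
        return grad[:, None]

    def simulate(self, rng, mu, extras):
        pi = expit(extras[0])
        y = rng.poisson(mu)
        return np.where(rng.random(np.size(mu)) < pi, 0, y)


class ZeroInflatedNegativeBinomial(_ZeroInflatedMixin, Family):
    name = "zi-nb"
    extra_names = ("log_phi", "logit_pi")

    def default_extras(self):
        return np.array([0.0, -1.0])

    def log_pmf(self, y, mu, extras):
        return self._mix(y, mu, nb_log_pmf(y, mu, np.exp(extras[0])), extras[1])

    def dlog_deta(self, y, mu, extras):
        y = np.asarray(y, dtype=float)
        phi = np.exp(extras[0])
        pi = expit(extras[1])
        p0 = _nb_p0(mu, phi)
        denom = pi + (1.0 - pi) * p0
        dp0_deta = p0 * (-phi * mu / (mu + phi))
        zero_case = (1.0 - pi) * dp0_deta / denom
        return np.where(y == 0, zero_case, _nb_dlog_deta(y, mu, phi))

    def dlog_dextras(self, y, mu, extras):
        y = np.asarray(y, dtype=float)
        phi = np.exp(extras[0])
        pi = expit(extras[1])
        dpi = pi * (1.0 - pi)
        p0 = _nb_p0(mu, phi)
        denom = pi + (1.0 - pi) * p0
        dlogp0_dphi = np.log(phi / (mu + phi)) + mu / (mu + phi)
        d_logphi = np.where(
            y == 0,
            (1.0 - pi) * p0 * dlogp0_dphi * phi / denom,
            _nb_dlog_dphi(y, mu, phi) * phi,
        )
        d_logitpi = np.where(y == 0, (1.0 - p0) * dpi / denom, -pi)
        return np.column_stack([d_logphi, d_logitpi])

    def extras_log_prior(self, extras):
        return NegativeBinomial().extras_log_prior(extras[:1])

    def extras_log_prior_grad(self, extras):
        g = np.zeros(2)
        g[0] = NegativeBinomial().extras_log_prior_grad(extras[:1])[0]
        return g

    def simulate(self, rng, mu, extras):
        phi = np.exp(extras[0])
        pi = expit(extras[1])
        lam = rng.gamma(shape=phi, scale=np.asarray(mu) / phi)
        y = rng.poisson(lam)
        return np.where(rng.random(np.size(mu)) < pi, 0, y)


class HurdleNegativeBinomial(Family):
    """Hurdle: zeros with probability pi0, positives from a zero-truncated NB."""

    name = "hurdle-nb"
    extra_names = ("log_phi", "logit_pi0")

    def default_extras(self):
        return np.array([0.0, 0.0])

    def log_pmf(self, y, mu, extras):
        y = _check_counts(y)
        phi = np.exp(extras[0])
        pi0 = expit(extras[1])
        base = nb_log_pmf(np.maximum(y, 1), mu, phi)
        p0 = _nb_p0(mu, phi)
        pos = np.log1p(-pi0) + base - np.log1p(-p0)
        return np.where(y == 0, np.log(pi0), pos)

    def dlog_deta(self, y, mu, extras):
        y = np.asarray(y, dtype=float)
        phi = np.exp(extras[0])
        p0 = _nb_p0(mu, phi)
        dp0_deta = p0 * (-phi * mu / (mu + phi))
        pos = _nb_dlog_deta(np.maximum(y, 1), mu, phi) + dp0_deta / (1.0 - p0)
        return np.where(y == 0, 0.0, pos)

    def dlog_dextras(self, y, mu, extras):
        y = np.asarray(y, dtype=float)
        phi = np.exp(extras[0])
        pi0 = expit(extras[1])
        p0 = _nb_p0(mu, phi)
        dlogp0_dphi = np.log(phi / (mu + phi)) + mu / (mu + phi)
        dphi_pos = _nb_dlog_dphi(np.maximum(y, 1), mu, phi) + p0 * dlogp0_dphi / (
            1.0 - p0
        )
        d_logphi = np.where(y == 0, 0.0, dphi_pos * phi)
        d_logitpi0 = np.where(y == 0, 1.0 - pi0, -pi0)
        return np.column_stack([d_logphi, d_logitpi0])

    def extras_log_prior(self, extras):
        return NegativeBinomial().extras_log_prior(extras[:1])

    def extras_log_prior_grad(self, extras):
        g = np.zeros(2)
        g[0] = NegativeBinomial().extras_log_prior_grad(extras[:1])[0]
        return g

    def simulate(self, rng, mu, extras):
        phi = np.exp(extras[0])
        pi0 = expit(extras[1])
        mu = np.asarray(mu, dtype=float)
        n = mu.size
        out = np.zeros(n, dtype=int)
        positive = rng.random(n) >= pi0
        # Rejection-sample the zero-truncated NB row-wise (vectorized rounds).
        idx = np.flatnonzero(positive)
        for _ in range(1000):
            if not idx.size:
                break
            lam = rng.gamma(shape=phi, scale=mu[idx] / phi)
            draw = rng.poisson(lam)
            ok = draw > 0
            out[idx[ok]] = draw[ok]
            idx = idx[~ok]
        out[idx] = 1  # vanishing acceptance probability: truncated mass sits at 1
        return out


FAMILIES: dict[str, Family] = {
    f.name: f
    for f in (
        Poisson(),
        NegativeBinomial(),
        ZeroInflatedPoisson(),
        ZeroInflatedNegativeBinomial(),
        HurdleNegativeBinomial(),
    )
}


def get_family(name: str | Family) -> Family:
    if isinstance(name, Family):
        return name
    try:
        return FAMILIES[name]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose from {sorted(FAMILIES)}"
        ) from None
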