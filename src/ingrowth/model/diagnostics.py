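"""MCMC convergence diagnostics: split rank-normalized R-hat and bulk ESS.

Implements the rank-normalized split-chain diagnostics of Vehtari et al.
(2021): chains are split in half, draws are rank-normalized with the
Blom-style offset, and the classic between/within variance ratio is taken as
the maximum of the bulk and folded (median-absolute-deviation) statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from ingrowth.model.sampler import PosteriorDraws

__all__ = ["FitDiagnostics", "split_rhat", "ess", "convergence"]


@dataclasses.dataclass
class FitDiagnostics:
    rhat: dict[str, float]
    ess: dict[str, float]
    max_rhat: float
    min_ess: float

    def converged(self, threshold: float = 1.01) -> bool:
        return self.max_rhat <= threshold


def _split_chains(chains: np.ndarray) -> np.ndarray:
    """(C, N) -> (2C, N//2), dropping the middle draw for odd N."""
    c, n = chains.shape
    half = n // 2
    return np.concatenate([chains[:, :half], chains[:, n - half :]], axis=0)

def _rank_normalize(chains: np.ndarray) -> np.ndarray:
    flat = chains.ravel()
    ranks = stats.rankdata(flat, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (flat.size + 0.25))
    return z.reshape(chains.shape)


def _basic_rhat(chains: np.ndarray) -> float:
    """Classic Gelman-Rubin on already-split chains (C, N)."""
    c, n = chains.shape
    if n < 2:
        return float("nan")
    chain_means = chains.mean(axis=1)
    chain_vars = chains.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return float("nan")
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def split_rhat(chains: np.ndarray) -> float:
    """Rank-normalized split R-hat of one parameter; chains is (C, N), C >= 2.

    Returns the maximum of the bulk statistic and the folded statistic
    (computed on |x - median|), as recommended for detecting both location
    and scale disagreement between chains.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    if np.allclose(chains, chains.ravel()[0]):
        return float("nan")
    split = _split_chains(chains)
    bulk = _basic_rhat(_rank_normalize(split))
    folded = _basic_rhat(_rank_normalize(np.abs(split - np.median(split))))
    return float(np.nanmax([bulk, folded]))


def ess(chains: np.ndarray) -> float:
    """Bulk effective sample size (rank-normalized, Geyer pairing)."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    if np.allclose(chains, chains.ravel()[0]):
        return float("nan")
    z = _rank_normalize(_split_chains(chains))
    c, n = z.shape
    if n < 4:
        return float("nan")
    chain_vars = z.var(axis=1, ddof=1)
    w = chain_vars.mean()
    var_plus = (n - 1) / n * w + n * z.mean(axis=1).var(ddof=1) / n
    acov = np.stack([_autocov(z[i]) for i in range(c)])  # (C, N)
    rho = 1.0 - (w - acov.mean(axis=0)) / var_plus
    # Geyer initial monotone positive sequence on paired sums
    # Gamma_k = rho_{2k} + rho_{2k+1}.
    pair_sums: list[float] = []
    t = 0
    while t + 1 < n:
        p = float(rho[t] + rho[t + 1])
        if p <= 0:
            break
        pair_sums.append(p)
        t += 2
    for i in range(1, len(pair_sums)):  # enforce monotone decrease
        pair_sums[i] = min(pair_sums[i], pair_sums[i - 1])
    tau = max(-1.0 + 2.0 * sum(pair_sums), 1.0 / np.log10(c * n + 10))
    return float(c * n / tau)


def _autocov(x: np.ndarray) -> np.ndarray:
    n = x.size
    xc = x - x.mean()
    size = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size)
    acov = np.fft.irfft(f * np.conj(f), size)[:n].real
    return acov / n


def convergence(draws: PosteriorDraws) -> FitDiagnostics:
    """Per-parameter R-hat and ESS across chains."""
    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require >= 2 chains")
    names = draws.names
    rhats: dict[str, float] = {}
    esses: dict[str, float] = {}
    for p, name in enumerate(names):
        chains = draws.draws[:, :, p]
        rhats[name] = split_rhat(chains)
        esses[name] = ess(chains)
    finite_r = [v for v in rhats.values() if np.isfinite(v)]
    finite_e = [v for v in esses.values() if np.isfinite(v)]
    return FitDiagnostics(
        rhat=rhats,
        ess=esses,
        max_rhat=float(np.max(finite_r)) if finite_r else float("nan"),
        min_ess=float(np.min(finite_e)) if finite_e else float("nan"),
    )
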