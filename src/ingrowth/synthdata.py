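"""Synthetic inventories with the statistical structure the analysis assumes.

Generates correlated plot covariates on realistic scales, a species pool with
trait values (grouped by the traits module), repeated tree lists that feed the
inventory module, and recruitment counts drawn from the hierarchical
negative-binomial generative model with known parameters.  A parameter
recovery harness replicates generate -> fit -> score loops.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` sub-streams (covariates, traits, trees, counts),
so every artifact is reproducible from the seed alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
import numpy as np
import pandas as pd

from ingrowth.model.design import DesignMatrix, build_design
from ingrowth.model.families import get_family
from ingrowth.model.params import ModelParameters, Priors
from ingrowth.model.sampler import FitConfig, PosteriorDraws, fit_posterior
from ingrowth import traits as traits_mod

__all__ = [
    "DESIGN_PRESETS",
    "GeneratorConfig",
    "SyntheticDataset",
    "default_true_parameters",
    "generate_covariates",
    "generate_species_traits",
    "generate_tree_lists",
    "simulate_counts",
    "make_dataset",
    "write_dataset",
    "recovery_experiment",
]

#: Inventory-design presets: recruitment DBH threshold (cm), plot-size range
#: (ha) and mean period length (yr) mimicking the four source inventories.
DESIGN_PRESETS: dict[str, dict[str, float | tuple[float, float]]] = {
    "CH-FR": {"dbh_threshold": 4.0, "plot_area": (0.03, 3.47), "period_mean": 12.2},
    "GER-FR": {"dbh_threshold": 7.0, "plot_area": (0.05, 0.10), "period_mean": 14.8},
    "FLAN-NFI": {"dbh_threshold": 7.0, "plot_area": (0.02, 0.03), "period_mean": 14.7},
    "CH-NFI": {"dbh_threshold": 12.0, "plot_area": (0.02, 0.02), "period_mean": 9.7},
}

#: Raw-scale covariate means and sds (basal_area, stem_density, sca, dds, wb, bs).
_COV_MEANS = np.array([32.0, 600.0, 3.5, 2400.0, 100.0, 30.0])
_COV_SDS = np.array([13.0, 350.0, 0.9, 500.0, 250.0, 8.0])
_COV_LOWER = np.array([0.5, 20.0, 1.0, 300.0, -400.0, 5.0])
_COV_UPPER = np.array([100.0, 3200.0, 5.0, 4400.0, 2200.0, 48.0])

#: Mild default correlation between the six covariates: stand variables
#: correlate with one another, and dds correlates with wb (warmer sites are
#: drier) without threatening the VIF < 10 screen.
_DEFAULT_CORR = np.array(
    [
        [1.00, 0.45, 0.30, 0.10, 0.00, 0.00],
        [0.45, 1.00, 0.15, 0.05, 0.00, 0.00],
        [0.30, 0.15, 1.00, 0.10, 0.00, 0.00],
        [0.10, 0.05, 0.10, 1.00, -0.45, 0.00],
        [0.00, 0.00, 0.00, -0.45, 1.00, 0.20],
        [0.00, 0.00, 0.00, 0.00, 0.20, 1.00],
    ]
)


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    n_plots: int = 200
    n_species: int = 10
    n_groups: int = 6
    n_periods: int = 1
    design_preset: str = "GER-FR"
    covariate_corr: np.ndarray = dataclasses.field(
        default_factory=lambda: _DEFAULT_CORR.copy()
    )
    covariate_means: np.ndarray = dataclasses.field(
        default_factory=lambda: _COV_MEANS.copy()
    )
    covariate_sds: np.ndarray = dataclasses.field(
        default_factory=lambda: _COV_SDS.copy()
    )
    # Tree-list generation knobs.
    density_range: tuple[float, float] = (200.0, 1200.0)
    growth_mean: float = 3.0  # cm DBH increment per period
    mortality: float = 0.05
    sapling_rate: float = 150.0  # sub-threshold stems per ha at census 1
    newtree_rate: float = 50.0  # stems per ha appearing by census 2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_plots, self.n_species, self.n_groups, self.n_periods) < 1:
            raise ValueError("all counts must be >= 1")
        corr = np.asarray(self.covariate_corr, dtype=float)
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.linalg.eigvalsh(corr) <= 0):
            raise ValueError("correlation matrix must be positive definite")
        if self.design_preset not in DESIGN_PRESETS:
            raise ValueError(
                f"unknown design preset {self.design_preset!r}; "
                f"choose from {sorted(DESIGN_PRESETS)}"
            )

    @property
    def preset(self) -> dict:
        return DESIGN_PRESETS[self.design_preset]

    @property
    def dbh_threshold(self) -> float:
        return float(self.preset["dbh_threshold"])

    def streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("covariates", "traits", "trees", "counts")
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclasses.dataclass
class SyntheticDataset:
    config: GeneratorConfig
    observations: pd.DataFrame
    stand: pd.DataFrame
    site_env: pd.DataFrame
    traits: pd.DataFrame
    groups: pd.DataFrame
    design: DesignMatrix
    truth: ModelParameters


def _plot_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def generate_covariates(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(stand, site_env) tables with correlated covariates.

    Draws one multivariate-normal vector per plot on the configured raw
    scales, clipped to plausible ranges.  Stand variables are repeated per
    period with small period-to-period noise; environmental variables are
    per plot.
    """
    rng = rng or config.streams()["covariates"]
    cov = (
        np.asarray(config.covariate_corr)
        * np.outer(config.covariate_sds, config.covariate_sds)
    )
    raw = rng.multivariate_normal(config.covariate_means, cov, size=config.n_plots)
    raw = np.clip(raw, _COV_LOWER, _COV_UPPER)
    plots = _plot_ids(config.n_plots)
    env = pd.DataFrame(
        {
            "plot_id": plots,
            "dds": raw[:, 3],
            "wb": raw[:, 4],
            "bs": raw[:, 5],
            "kpmod": np.ones(config.n_plots),
        }
    )
    stand_rows = []
    for t in range(config.n_periods):
        jitter = rng.normal(1.0, 0.03, size=(config.n_plots, 3)) if t else 1.0
        vals = raw[:, :3] * jitter
        vals = np.clip(vals, _COV_LOWER[:3], _COV_UPPER[:3])
        stand_rows.append(
            pd.DataFrame(
                {
                    "plot_id": plots,
                    "period_id": f"{t}-{t + 1}",
                    "basal_area": vals[:, 0],
                    "stem_density": vals[:, 1],
                    "sca": vals[:, 2],
                }
            )
        )
    return pd.concat(stand_rows, ignore_index=True), env


def generate_species_traits(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(traits table, group assignment) for a synthetic species pool.

    Trait values are uniform on [1, 5]; grouping runs through the traits
    module with k centroids spread over the scaled trait plane.
    """
    rng = rng or config.streams()["traits"]
    species = [f"SP{j:02d}" for j in range(config.n_species)]
    k = config.n_groups
    if k == 6:
        centroids = np.asarray(traits_mod.DEFAULT_CENTROIDS, dtype=float)
    else:
        angles = np.linspace(0, 2 * np.pi, k, endpoint=False)
        centroids = np.column_stack([2.0 * np.cos(angles), 2.0 * np.sin(angles)])
    shade = rng.uniform(1, 5, config.n_species)
    drought = rng.uniform(1, 5, config.n_species)
    # Anchor the first k species near the k centroids (mapped back from the
    # scaled plane assuming uniform-[1,5] moments) so no group starts empty.
    n_anchor = min(k, config.n_species)
    raw_anchor = 3.0 + centroids[:n_anchor] * (4.0 / np.sqrt(12.0)) / 2.0
    drought[:n_anchor] = raw_anchor[:, 0] + rng.normal(0, 0.02, n_anchor)
    shade[:n_anchor] = raw_anchor[:, 1] + rng.normal(0, 0.02, n_anchor)
    table = pd.DataFrame(
        {
            "species": species,
            "genus": [f"G{j % max(2, config.n_species // 2):02d}" for j in range(config.n_species)],
            "shade_tol": np.clip(shade, 1, 5).round(2),
            "drought_tol": np.clip(drought, 1, 5).round(2),
            "sca": rng.uniform(1, 5, config.n_species).round(2),
        }
    )
    assignments, _ = traits_mod.group_species(table, centroids)
    groups = assignments[["species", "group_label"]]
    return table, groups


def default_true_parameters(
    design: DesignMatrix,
    sigma_plot: float = 0.4,
    sigma_species: float = 0.3,
    sigma_slope: float = 0.15,
    phi: float = 1.2,
    rng: np.random.Generator | None = None,
) -> ModelParameters:
    """Ground-truth parameters with qualitatively realistic group effects.

    Negative basal-area and SCA effects that weaken (SCA: flip sign) with
    increasing group index, positive stem-density and degree-day effects,
    weak water effects and a small positive basal-area x density interaction.
    Illustrative, not calibrated to any fitted values.
    """
    rng = rng or np.random.default_rng(12345)
    G, P = design.n_groups, design.n_cols
    grade = np.linspace(0, 1, G)  # proxy for increasing shade tolerance
    base = {
        "basal_area": -0.5 + 0.4 * grade,
        "stem_density": 0.3 + 0.0 * grade,
        "sca": -0.5 + 1.0 * grade,
        "dds": 0.25 + 0.0 * grade,
        "wb": 0.05 + 0.0 * grade,
        "bs": 0.1 + 0.0 * grade,
        "basal_area:stem_density": 0.15 + 0.0 * grade,
        "wb:bs": 0.05 + 0.0 * grade,
    }
    beta = np.zeros((G, P))
    for p, col in enumerate(design.columns):
        beta[:, p] = base.get(col, np.zeros(G))
    return ModelParameters(
        beta0=np.full(G, -0.5) + rng.normal(0, 0.2, G),
        beta=beta,
        u0_plot=np.zeros(design.n_plots),
        u0_species=np.zeros(design.n_species),
        u_species=np.zeros((design.n_species, P)),
        sigma_plot=sigma_plot,
        sigma_species=sigma_species,
        sigma_slopes=np.full(P, sigma_slope),
        phi=phi,
    )


def simulate_counts(
    design: DesignMatrix,
    truth: ModelParameters,
    seed: int | np.random.Generator = 0,
    family: str = "nb",
    draw_random_effects: bool = True,
) -> tuple[np.ndarray, ModelParameters]:
    """Draw counts from the generative model.

    With ``draw_random_effects`` (default) plot/species effects are drawn
    fresh from their normal laws at the truth's scales; the realized effects
    are returned inside the second element so they can be scored.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    params = truth
    if draw_random_effects:
        P = design.n_cols
        params = dataclasses.replace(
            truth,
            u0_plot=rng.normal(0, truth.sigma_plot, design.n_plots),
            u0_species=rng.normal(0, truth.sigma_species, design.n_species),
            u_species=rng.normal(
                0, np.asarray(truth.sigma_slopes)[None, :], (design.n_species, P)
            ),
        )
    eta = params.linear_predictor(design)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor in the generative model")
    mu = np.exp(eta)
    fam = get_family(family)
    extras = fam.default_extras()
    for i, name in enumerate(fam.extra_names):
        if name == "log_phi":
            extras[i] = np.log(params.phi)
    y = fam.simulate(rng, mu, extras)
    return np.asarray(y, dtype=int), params


def make_dataset(
    config: GeneratorConfig | None = None,
    truth: ModelParameters | None = None,
    species_pool: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> SyntheticDataset:
    """Full generative pipeline: covariates -> design -> counts.

    ``species_pool`` optionally supplies a fixed (traits, groups) pair so
    replicate experiments can hold the group structure constant while
    covariates, random effects and counts are redrawn.
    """
    config = config or GeneratorConfig()
    streams = config.streams()
    stand, env = generate_covariates(config, streams["covariates"])
    if species_pool is None:
        traits_table, groups = generate_species_traits(config, streams["traits"])
    else:
        traits_table, groups = species_pool
    area_lo, area_hi = config.preset["plot_area"]
    rng = streams["counts"]
    plots = _plot_ids(config.n_plots)
    areas = rng.uniform(area_lo, area_hi, config.n_plots)
    period_mean = float(config.preset["period_mean"])
    obs_rows = []
    for t in range(config.n_periods):
        period_id = f"{t}-{t + 1}"
        lengths = np.clip(rng.normal(period_mean, 2.0, config.n_plots), 3.0, 30.0)
        for i, plot in enumerate(plots):
            for sp in traits_table["species"]:
                obs_rows.append(
                    {
                        "plot_id": plot,
                        "period_id": period_id,
                        "species": sp,
                        "count": 0,
                        "plot_area_ha": areas[i],
                        "period_length_yr": lengths[i],
                    }
                )
    observations = pd.DataFrame(obs_rows)
    design = build_design(observations, stand, env, groups)
    if truth is None:
        truth = default_true_parameters(design)
    y, realized = simulate_counts(design, truth, rng)
    design = dataclasses.replace(design, y=y)
    observations = observations.copy()
    observations["count"] = y
    return SyntheticDataset(
        config=config,
        observations=observations,
        stand=stand,
        site_env=env,
        traits=traits_table,
        groups=groups,
        design=design,
        truth=realized,
    )


def generate_tree_lists(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """(trees, plots, targets) tables for the inventory pipeline.

    Census-1 DBH follows threshold + Gamma (right-skewed); census-2 DBH adds
    positive growth increments; saplings below the threshold and entirely new
    stems create genuine recruits.  ``targets`` reports each plot's expected
    basal area and stem density for calibration checks.
    """
    rng = rng or config.streams()["trees"]
    thr = config.dbh_threshold
    area_lo, area_hi = config.preset["plot_area"]
    species = [f"SP{j:02d}" for j in range(config.n_species)]
    shape, scale = 1.6, 7.0  # census-1 DBH excess over the threshold
    mean_sq = (thr + shape * scale) ** 2 + shape * scale**2
    rows: list[dict] = []
    plot_rows: list[dict] = []
    target_rows: list[dict] = []
    for i in range(config.n_plots):
        plot = f"P{i:04d}"
        area = rng.uniform(area_lo, area_hi)
        density = rng.uniform(*config.density_range)
        n1 = max(1, int(round(density * area)))
        dbh1 = thr + rng.gamma(shape, scale, n1)
        sp1 = rng.choice(species, n1)
        n_sap = rng.poisson(config.sapling_rate * area)
        sap_dbh = rng.uniform(max(0.5, thr - 3.0), thr - 0.05, n_sap)
        sap_sp = rng.choice(species, n_sap)
        tree_id = 0
        census1: list[tuple[str, str, float]] = []
        for dbh, sp in zip(np.concatenate([dbh1, sap_dbh]), np.concatenate([sp1, sap_sp])):
            census1.append((f"{plot}-T{tree_id:05d}", str(sp), float(dbh)))
            tree_id += 1
        for tid, sp, dbh in census1:
            rows.append(
                {
                    "plot_id": plot,
                    "census_id": 1,
                    "census_date": "2000-06-01",
                    "tree_id": tid,
                    "species": sp,
                    "dbh_cm": round(dbh, 2),
                }
            )
        survivors = rng.random(len(census1)) >= config.mortality
        growth = rng.gamma(2.0, config.growth_mean / 2.0, len(census1))
        for keep, (tid, sp, dbh), inc in zip(survivors, census1, growth):
            if not keep:
                continue
            rows.append(
                {
                    "plot_id": plot,
                    "census_id": 2,
                    "census_date": "2012-06-01",
                    "tree_id": tid,
                    "species": sp,
                    "dbh_cm": round(dbh + inc, 2),
                }
            )
        n_new = rng.poisson(config.newtree_rate * area)
        for k in range(n_new):
            rows.append(
                {
                    "plot_id": plot,
                    "census_id": 2,
                    "census_date": "2012-06-01",
                    "tree_id": f"{plot}-N{k:05d}",
                    "species": str(rng.choice(species)),
                    "dbh_cm": round(float(rng.uniform(thr - 2.0, thr + 4.0)), 2),
                }
            )
        plot_rows.append({"plot_id": plot, "plot_area_ha": round(area, 4)})
        target_rows.append(
            {
                "plot_id": plot,
                "density_target": n1 / area,
                "ba_target": n1 * np.pi * mean_sq / 200.0**2 / area,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(plot_rows), pd.DataFrame(target_rows)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write the dataset in the same plain-text formats real data would use."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.observations.to_csv(out / "observations.csv", index=False)
    dataset.stand.to_csv(out / "stand.csv", index=False)
    dataset.site_env.to_csv(out / "site_env.csv", index=False)
    dataset.traits.to_csv(out / "traits.csv", index=False)
    dataset.groups.to_csv(out / "groups.csv", index=False)
    truth = dataset.truth
    payload = {
        "beta0": truth.beta0.tolist(),
        "beta": truth.beta.tolist(),
        "u0_plot": truth.u0_plot.tolist(),
        "u0_species": truth.u0_species.tolist(),
        "u_species": truth.u_species.tolist(),
        "sigma_plot": truth.sigma_plot,
        "sigma_species": truth.sigma_species,
        "sigma_slopes": truth.sigma_slopes.tolist(),
        "phi": truth.phi,
        "columns": list(dataset.design.columns),
        "group_labels": list(dataset.design.group_labels),
        "seed": dataset.config.seed,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2))


def recovery_experiment(
    config: GeneratorConfig | None = None,
    n_replicates: int = 20,
    fit_config: FitConfig | None = None,
    priors: Priors | None = None,
) -> pd.DataFrame:
    """Replicate generate -> fit -> score loops.

    Per replicate, a fresh dataset is simulated (new seed derived from the
    config seed) over a fixed species pool, the model is fitted, and every
    group-level coefficient, the dispersion and the random-effect scales are
    scored for bias and 95% interval coverage.  Returns one row per parameter
    block with columns coverage, bias, rmse, mc_sd (sd of the estimates
    across replicates) and n_scored; per-coefficient detail is attached as
    ``frame.attrs["per_coefficient"]``.
    """
    config = config or GeneratorConfig(n_plots=200, n_species=10)
    fit_config = fit_config or FitConfig(
        chains=2, iterations=400, warmup=200, retained=600, method="map_laplace"
    )
    species_pool = generate_species_traits(config)
    records: list[dict] = []
    failures = 0
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=config.seed + 1000 + r)
        try:
            dataset = make_dataset(cfg, species_pool=species_pool)
            fc = dataclasses.replace(fit_config, seed=fit_config.seed + r)
            draws = fit_posterior(dataset.design, config=fc, priors=priors)
            records.extend(_score_replicate(r, dataset, draws))
        except Exception:  # noqa: BLE001 - a failed replicate is recorded, not fatal
            failures += 1
    if not records:
        raise RuntimeError("all recovery replicates failed")
    frame = pd.DataFrame(records)
    out = []
    for block, sub in frame.groupby("block"):
        out.append(
            {
                "block": block,
                "coverage": float(sub["covered"].mean()),
                "bias": float((sub["estimate"] - sub["true"]).mean()),
                "rmse": float(np.sqrt(((sub["estimate"] - sub["true"]) ** 2).mean())),
                "mc_sd": float(sub["estimate"].std(ddof=1)),
                "n_scored": int(len(sub)),
                "n_failed_replicates": failures,
            }
        )
    report = pd.DataFrame(out)
    per_coef = (
        frame.groupby(["block", "coef"])
        .apply(
            lambda s: pd.Series(
                {
                    "bias": (s["estimate"] - s["true"]).mean(),
                    "mc_sd": s["estimate"].std(ddof=1),
                    "coverage": s["covered"].mean(),
                    "n": len(s),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    report.attrs["per_coefficient"] = per_coef
    return report


def _score_replicate(r: int, dataset: SyntheticDataset, draws: PosteriorDraws):
    layout = draws.layout
    flat = draws.flat()
    truth = dataset.truth
    records = []

    design = dataset.design

    def score(block: str, coef: str, samples: np.ndarray, true_val: float) -> None:
        lo, hi = np.quantile(samples, [0.025, 0.975])
        records.append(
            {
                "replicate": r,
                "block": block,
                "coef": coef,
                "estimate": float(np.mean(samples)),
                "true": float(true_val),
                "covered": bool(lo <= true_val <= hi),
            }
        )

    G, P = layout.n_groups, layout.n_cols
    beta0 = flat[:, layout.slices["beta0"]]
    beta = flat[:, layout.slices["beta"]].reshape(-1, G, P)
    for g in range(G):
        glabel = design.group_labels[g]
        score("beta0", glabel, beta0[:, g], truth.beta0[g])
        for p in range(P):
            score(
                "beta",
                f"{glabel}:{design.columns[p]}",
                beta[:, g, p],
                truth.beta[g, p],
            )
    if "log_phi" in layout.family.extra_names:
        i = layout.family.extra_names.index("log_phi")
        score("phi", "phi", np.exp(flat[:, layout.slices["extras"]][:, i]), truth.phi)
    score(
        "sigma_plot",
        "sigma_plot",
        np.exp(flat[:, layout.slices["log_sigma_plot"]][:, 0]),
        truth.sigma_plot,
    )
    score(
        "sigma_species",
        "sigma_species",
        np.exp(flat[:, layout.slices["log_sigma_species"]][:, 0]),
        truth.sigma_species,
    )
    return records
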