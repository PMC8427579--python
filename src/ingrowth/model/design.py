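"""Standardized design matrix with offsets, interactions and VIF screening."""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MAIN_VARIABLES", "DesignMatrix", "build_design", "vif"]

#: The six main explanatory variables, in canonical order.
MAIN_VARIABLES = ("basal_area", "stem_density", "sca", "dds", "wb", "bs")

#: Interaction columns formed from standardized mains.
_INTERACTIONS = (
    ("basal_area:stem_density", "basal_area", "stem_density"),
    ("wb:bs", "wb", "bs"),
)


@dataclasses.dataclass(frozen=True)
class DesignMatrix:
    """One row per (plot, period, species) observation.

    ``X`` holds z-standardized main-effect columns followed by interaction
    products of standardized mains; ``offset`` is ``log(plot_area *
    period_length)``.  Integer index arrays map rows to plots, species and
    trait groups.
    """

    y: np.ndarray  # (n,) observed counts
    X: np.ndarray  # (n, p) standardized covariates
    columns: tuple[str, ...]
    offset: np.ndarray  # (n,)
    plot_idx: np.ndarray  # (n,) int
    species_idx: np.ndarray  # (n,) int
    group_idx: np.ndarray  # (n,) int
    plot_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    main_columns: tuple[str, ...]
    scale_means: dict[str, float]  # raw mean per main, for back-transforms
    scale_sds: dict[str, float]

    def __post_init__(self) -> None:
        n = len(self.y)
        for name in ("X", "offset", "plot_idx", "species_idx", "group_idx"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match y")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("columns do not match X width")
        if not np.all(np.isfinite(self.offset)):
            raise ValueError("offset must be finite")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_plots(self) -> int:
        return len(self.plot_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.columns.index(name)]

    def species_group(self) -> np.ndarray:
        """Group index per species (species are nested in trait groups)."""
        out = np.full(self.n_species, -1, dtype=int)
        out[self.species_idx] = self.group_idx
        return out


def _standardize(values: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=0))
    if sd == 0:
        raise ValueError(f"covariate {name!r} has zero variance")
    return (values - mean) / sd, mean, sd


def build_design(
    observations: pd.DataFrame,
    stand: pd.DataFrame,
    site_env: pd.DataFrame,
    groups: pd.DataFrame,
    drop_variables: Sequence[str] = (),
) -> DesignMatrix:
    """Merge the pipeline tables into a standardized design matrix.

    Parameters
    ----------
    observations : DataFrame
        plot_id, period_id, species, count, plot_area_ha, period_length_yr.
    stand : DataFrame
        plot_id, period_id, basal_area, stem_density, sca.
    site_env : DataFrame
        plot_id, dds, wb, bs.
    groups : DataFrame
        species, group_label.
    drop_variables : sequence of str
        Main variables to exclude; dropping ``wb`` also drops the ``wb:bs``
        interaction (collinearity screen outcome for one data set).
    """
    merged = observations.merge(stand, on=["plot_id", "period_id"], how="left")
    merged = merged.merge(
        site_env[["plot_id", "dds", "wb", "bs"]], on="plot_id", how="left"
    )
    merged = merged.merge(
        groups[["species", "group_label"]], on="species", how="left"
    )
    mains = [m for m in MAIN_VARIABLES if m not in set(drop_variables)]
    missing_cov = merged[mains].isna().any(axis=1)
    if missing_cov.any():
        bad = merged.loc[missing_cov, ["plot_id", "period_id", "species"]]
        raise ValueError(
            "missing covariates for rows:\n" + bad.drop_duplicates().to_string()
        )
    if merged["group_label"].isna().any():
        bad = sorted(merged.loc[merged["group_label"].isna(), "species"].unique())
        raise ValueError(f"species without a trait group: {bad}")

    cols: list[np.ndarray] = []
    names: list[str] = []
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for m in mains:
        z, mean, sd = _standardize(merged[m].to_numpy(dtype=float), m)
        cols.append(z)
        names.append(m)
        means[m], sds[m] = mean, sd
    for label, a, b in _INTERACTIONS:
        if a in names and b in names:
            cols.append(cols[names.index(a)] * cols[names.index(b)])
            names.append(label)

    offset = np.log(
        merged["plot_area_ha"].to_numpy(dtype=float)
        * merged["period_length_yr"].to_numpy(dtype=float)
    )

    plot_ids = tuple(sorted(merged["plot_id"].astype(str).unique()))
    species_ids = tuple(sorted(merged["species"].astype(str).unique()))
    group_labels = tuple(sorted(merged["group_label"].astype(str).unique()))
    plot_lookup = {p: i for i, p in enumerate(plot_ids)}
    species_lookup = {s: i for i, s in enumerate(species_ids)}
    group_lookup = {g: i for i, g in enumerate(group_labels)}

    return DesignMatrix(
        y=merged["count"].to_numpy(dtype=int),
        X=np.column_stack(cols),
        columns=tuple(names),
        offset=offset,
        plot_idx=merged["plot_id"].astype(str).map(plot_lookup).to_numpy(dtype=int),
        species_idx=merged["species"].astype(str).map(species_lookup).to_numpy(int),
        group_idx=merged["group_label"].astype(str).map(group_lookup).to_numpy(int),
        plot_ids=plot_ids,
        species_ids=species_ids,
        group_labels=group_labels,
        main_columns=tuple(mains),
        scale_means=means,
        scale_sds=sds,
    )


def vif(design: DesignMatrix | np.ndarray, columns: Sequence[str] | None = None):
    """Variance inflation factors: ``1 / (1 - R^2)`` per column.

    By default only the main-effect columns are screened (interactions are
    products of mains and inflate by construction).  Exactly collinear
    columns are reported as ``inf``.
    """
    if isinstance(design, DesignMatrix):
        names = list(columns if columns is not None else design.main_columns)
        mat = np.column_stack([design.column(c) for c in names])
    else:
        mat = np.asarray(design, dtype=float)
        names = list(columns) if columns is not None else [
            f"x{i}" for i in range(mat.shape[1])
        ]
    n, p = mat.shape
    if p < 2:
        raise ValueError("VIF needs at least 2 columns")
    out: dict[str, float] = {}
    for m in range(p):
        target = mat[:, m]
        others = np.column_stack(
            [np.ones(n), np.delete(mat, m, axis=1)]
        )
        coef, _, _, _ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_tot = float(np.sum((target - target.mean()) ** 2))
        ss_res = float(np.sum(resid**2))
        if ss_tot == 0:
            out[names[m]] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[names[m]] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
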