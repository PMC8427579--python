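"""Recruitment counts and stand-structure covariates from repeated tree lists.

A recruit is a tree that exceeds the calipering (DBH) threshold for the first
time between two consecutive censuses.  Stand attributes (basal area, stem
density, basal-area-weighted shade-casting ability) describe the second
census with the current period's recruits excluded.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TreeRecord",
    "CensusPair",
    "RecruitmentObservation",
    "StandState",
    "count_recruits",
    "stand_attributes",
    "plot_sca",
    "basal_area_m2",
    "build_observations",
    "harmonize_threshold",
]


@dataclasses.dataclass(frozen=True)
class TreeRecord:
    """One measured stem at one census."""

    plot_id: str
    census_id: int
    tree_id: str
    species: str
    dbh: float  # cm, > 0

    def __post_init__(self) -> None:
        if not self.dbh > 0:
            raise ValueError(f"dbh must be > 0, got {self.dbh} (tree {self.tree_id})")


@dataclasses.dataclass(frozen=True)
class CensusPair:
    """Two consecutive censuses of a plot, with exposure components."""

    plot_id: str
    census_1: int
    census_2: int
    period_length: float  # years
    plot_area: float  # ha

    def __post_init__(self) -> None:
        if self.census_2 <= self.census_1:
            raise ValueError("census_2 must come after census_1")
        if not self.period_length > 0:
            raise ValueError(f"period_length must be > 0, got {self.period_length}")
        if not self.plot_area > 0:
            raise ValueError(f"plot_area must be > 0, got {self.plot_area}")

    @property
    def period_id(self) -> str:
        return f"{self.census_1}-{self.census_2}"


@dataclasses.dataclass(frozen=True)
class RecruitmentObservation:
    """Count of new recruits for one plot x period x species."""

    plot_id: str
    period_id: str
    species: str
    count: int
    plot_area: float
    period_length: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if not (self.plot_area > 0 and self.period_length > 0):
            raise ValueError("offset components must be strictly positive")


@dataclasses.dataclass(frozen=True)
class StandState:
    """Stand-structure covariates for one plot x period."""

    plot_id: str
    period_id: str
    basal_area: float  # m^2 / ha
    stem_density: float  # 1 / ha
    sca: float | None  # [1, 5] or None for an empty stand


def basal_area_m2(dbh_cm: float) -> float:
    """Cross-sectional stem area (m^2) at breast height from DBH in cm."""
    return math.pi * (dbh_cm / 200.0) ** 2


def recruit_ids(
    trees_1: Sequence[TreeRecord],
    trees_2: Sequence[TreeRecord],
    dbh_threshold: float,
) -> set[str]:
    """Tree ids recruiting between the censuses at the given threshold.

    A tree recruits iff its census-2 DBH is >= threshold and it was either
    absent at census 1 or below the threshold there.  Trees that die between
    censuses never recruit.
    """
    if not dbh_threshold > 0:
        raise ValueError(f"dbh_threshold must be > 0, got {dbh_threshold}")
    dbh_1 = {t.tree_id: t.dbh for t in trees_1}
    out: set[str] = set()
    for tree in trees_2:
        if tree.dbh < dbh_threshold:
            continue
        prior = dbh_1.get(tree.tree_id)
        if prior is None or prior < dbh_threshold:
            out.add(tree.tree_id)
    return out


def count_recruits(
    pair: CensusPair,
    trees_1: Sequence[TreeRecord],
    trees_2: Sequence[TreeRecord],
    dbh_threshold: float,
    species_universe: Iterable[str] | None = None,
) -> list[RecruitmentObservation]:
    """Per-species recruitment counts for one census pair.

    Explicit zero-count rows are emitted for every species in
    ``species_universe`` (the count model needs the zeros); species outside
    the universe but present in the recruit set are appended as well.
    """
    _check_trees(pair, trees_1, pair.census_1)
    _check_trees(pair, trees_2, pair.census_2)
    ids = recruit_ids(trees_1, trees_2, dbh_threshold)
    counts: dict[str, int] = {}
    for tree in trees_2:
        if tree.tree_id in ids:
            counts[tree.species] = counts.get(tree.species, 0) + 1
    universe = list(species_universe) if species_universe is not None else sorted(counts)
    for sp in sorted(set(counts) - set(universe)):
        universe.append(sp)
    return [
        RecruitmentObservation(
            plot_id=pair.plot_id,
            period_id=pair.period_id,
            species=sp,
            count=counts.get(sp, 0),
            plot_area=pair.plot_area,
            period_length=pair.period_length,
        )
        for sp in universe
    ]


def _check_trees(
    pair: CensusPair, trees: Sequence[TreeRecord], census_id: int
) -> None:
    for t in trees:
        if t.plot_id != pair.plot_id or t.census_id != census_id:
            raise ValueError(
                f"tree {t.tree_id!r} (plot {t.plot_id!r}, census {t.census_id}) does "
                f"not belong to plot {pair.plot_id!r} census {census_id}"
            )


def stand_attributes(
    trees_2: Sequence[TreeRecord],
    recruits: set[str],
    pair: CensusPair,
    dbh_threshold: float,
) -> tuple[float, float]:
    """(basal_area m^2/ha, stem_density 1/ha) over non-recruit calipered trees."""
    if not pair.plot_area > 0:
        raise ValueError("plot_area must be > 0")
    standing = [
        t for t in trees_2 if t.tree_id not in recruits and t.dbh >= dbh_threshold
    ]
    if not standing:
        if trees_2:
            logger.warning(
                "all census-2 trees of plot %s are recruits; stand attributes set to 0",
                pair.plot_id,
            )
        return 0.0, 0.0
    ba = sum(basal_area_m2(t.dbh) for t in standing) / pair.plot_area
    return ba, len(standing) / pair.plot_area


def plot_sca(
    trees: Sequence[TreeRecord], species_sca: Mapping[str, float]
) -> float | None:
    """Basal-area-weighted mean shade-casting ability of a tree list.

    Returns None (flagged missing) for an empty list.  Raises if any species
    lacks an SCA value.
    """
    if not trees:
        return None
    ba_by_species: dict[str, float] = {}
    for t in trees:
        ba_by_species[t.species] = ba_by_species.get(t.species, 0.0) + basal_area_m2(
            t.dbh
        )
    missing = sorted(sp for sp in ba_by_species if sp not in species_sca)
    if missing:
        raise KeyError(f"species without SCA value: {missing}")
    total = sum(ba_by_species.values())
    return sum(species_sca[sp] * ba for sp, ba in ba_by_species.items()) / total


def build_observations(
    trees: pd.DataFrame,
    plots: pd.DataFrame,
    species_sca: Mapping[str, float],
    dbh_threshold: float,
    species_universe: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full inventory pipeline over tabular tree lists.

    Parameters
    ----------
    trees : DataFrame
        Columns plot_id, census_id, census_date, tree_id, species, dbh_cm.
    plots : DataFrame
        Columns plot_id, plot_area_ha.
    species_sca : mapping
        Species -> SCA value in [1, 5].
    dbh_threshold : float
        Calipering threshold in cm.
    species_universe : iterable of str, optional
        Species for which explicit zero rows are emitted; defaults to all
        species in ``trees``.

    Returns
    -------
    (observations, stand) : tuple of DataFrame
        ``observations`` has one row per plot x period x species with columns
        plot_id, period_id, species, count, plot_area_ha, period_length_yr;
        ``stand`` has plot_id, period_id, basal_area, stem_density, sca.
    """
    if species_universe is None:
        species_universe = sorted(trees["species"].unique())
    else:
        species_universe = list(species_universe)
    area = plots.set_index("plot_id")["plot_area_ha"].to_dict()
    trees = trees.copy()
    trees["census_date"] = pd.to_datetime(trees["census_date"])
    obs_rows: list[dict] = []
    stand_rows: list[dict] = []
    for plot_id, plot_trees in trees.groupby("plot_id", sort=True):
        if plot_id not in area:
            raise KeyError(f"plot {plot_id!r} missing from the plots table")
        census_dates = (
            plot_trees.drop_duplicates("census_id")
            .set_index("census_id")["census_date"]
            .sort_index()
        )
        census_ids = list(census_dates.index)
        by_census = {
            cid: _records_for(plot_trees, plot_id, cid) for cid in census_ids
        }
        for c1, c2 in zip(census_ids[:-1], census_ids[1:]):
            dt_years = (census_dates[c2] - census_dates[c1]).days / 365.25
            pair = CensusPair(
                plot_id=plot_id,
                census_1=c1,
                census_2=c2,
                period_length=dt_years,
                plot_area=float(area[plot_id]),
            )
            observations = count_recruits(
                pair, by_census[c1], by_census[c2], dbh_threshold, species_universe
            )
            ids = recruit_ids(by_census[c1], by_census[c2], dbh_threshold)
            ba, density = stand_attributes(by_census[c2], ids, pair, dbh_threshold)
            non_recruits = [
                t
                for t in by_census[c2]
                if t.tree_id not in ids and t.dbh >= dbh_threshold
            ]
            sca = plot_sca(non_recruits, species_sca)
            obs_rows.extend(
                {
                    "plot_id": o.plot_id,
                    "period_id": o.period_id,
                    "species": o.species,
                    "count": o.count,
                    "plot_area_ha": o.plot_area,
                    "period_length_yr": o.period_length,
                }
                for o in observations
            )
            stand_rows.append(
                {
                    "plot_id": plot_id,
                    "period_id": pair.period_id,
                    "basal_area": ba,
                    "stem_density": density,
                    "sca": np.nan if sca is None else sca,
                }
            )
    return pd.DataFrame(obs_rows), pd.DataFrame(stand_rows)


def _records_for(frame: pd.DataFrame, plot_id: str, census_id: int) -> list[TreeRecord]:
    sub = frame[frame["census_id"] == census_id]
    return [
        TreeRecord(
            plot_id=plot_id,
            census_id=int(census_id),
            tree_id=str(r.tree_id),
            species=str(r.species),
            dbh=float(r.dbh_cm),
        )
        for r in sub.itertuples(index=False)
    ]


def harmonize_threshold(
    trees: pd.DataFrame,
    plots: pd.DataFrame,
    species_sca: Mapping[str, float],
    native_threshold: float,
    new_threshold: float,
    mode: str = "both",
    species_universe: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recompute the dataset as if calipering had started at ``new_threshold``.

    ``mode='both'`` recomputes explanatory variables and the recruitment
    response at the new threshold; ``mode='explanatory'`` recomputes only the
    stand variables and keeps the response at the native threshold.
    """
    if new_threshold < native_threshold:
        raise ValueError(
            f"new_threshold {new_threshold} is below the native threshold "
            f"{native_threshold}"
        )
    if mode not in ("both", "explanatory"):
        raise ValueError(f"mode must be 'both' or 'explanatory', got {mode!r}")
    obs_native, _ = build_observations(
        trees, plots, species_sca, native_threshold, species_universe
    )
    obs_new, stand_new = build_observations(
        trees, plots, species_sca, new_threshold, species_universe
    )
    if mode == "explanatory":
        return obs_native, stand_new
    return obs_new, stand_new
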