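"""Trait-based species groups.

Species are placed in a two-dimensional (drought tolerance, shade tolerance)
space, rescaled to mean 0 / sd 2 per axis, and clustered with Lloyd k-means
seeded at fixed initial centroids.  Groups are labeled ``D<d>S<s>`` from the
rounded mean tolerances of their members on the original 1-5 scale.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesTraits",
    "TraitGroup",
    "DEFAULT_CENTROIDS",
    "scale_traits",
    "lloyd_kmeans",
    "assign_trait_groups",
    "label_groups",
    "genus_fallback",
    "group_species",
]

#: Default initial centroids in the scaled (drought, shade) plane: four points
#: on the shade<->drought diagonal plus two drought-intolerant points at
#: medium and low shade tolerance.  Approximate by construction; override via
#: configuration for a specific trait table.
DEFAULT_CENTROIDS: tuple[tuple[float, float], ...] = (
    (3.0, -2.5),  # very drought tolerant, light demanding
    (1.0, -1.0),
    (-0.5, 0.8),
    (-2.0, 2.5),  # very shade tolerant, drought intolerant
    (-1.5, 0.0),  # drought intolerant, medium shade
    (-1.5, -2.0),  # drought intolerant, low shade
)


@dataclasses.dataclass(frozen=True)
class SpeciesTraits:
    species: str
    genus: str
    shade_tol: float | None  # juvenile shade tolerance, [1, 5]
    drought_tol: float | None  # [1, 5]
    sca: float | None  # shade casting ability, [1, 5]

    def __post_init__(self) -> None:
        for name in ("shade_tol", "drought_tol", "sca"):
            v = getattr(self, name)
            if v is not None and not 1 <= v <= 5:
                raise ValueError(f"{name} must lie in [1, 5], got {v}")


@dataclasses.dataclass(frozen=True)
class TraitGroup:
    label: str
    members: frozenset[str]
    centroid: tuple[float, float]  # (drought_scaled, shade_scaled)


def scale_traits(values: Sequence[float], target_sd: float = 2.0) -> np.ndarray:
    """Center a trait column to mean 0 and rescale to the target sd.

    Population (divide-by-n) standard deviation, so a symmetric two-point
    column {1, 5} maps exactly to {-2, +2}.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to scale a trait column")
    sd = x.std()  # population convention
    if sd == 0:
        raise ValueError("constant trait column cannot be scaled")
    return (x - x.mean()) / sd * target_sd


def lloyd_kmeans(
    points: np.ndarray,
    initial_centroids: np.ndarray,
    max_iter: int = 300,
    tol: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic Lloyd k-means from fixed initial centroids.

    Returns ``(labels, centroids)``.  Empty clusters keep their previous
    centroid (and end up empty in the output) with a logged warning.
    """
    pts = np.asarray(points, dtype=float)
    centroids = np.asarray(initial_centroids, dtype=float).copy()
    if centroids.ndim != 2 or centroids.shape[1] != pts.shape[1]:
        raise ValueError("initial_centroids must be (k, n_dims)")
    if len(np.unique(centroids, axis=0)) != len(centroids):
        raise ValueError("initial centroids must be distinct")
    k = len(centroids)
    labels = np.zeros(len(pts), dtype=int)
    for _ in range(max_iter):
        dists = np.linalg.norm(pts[:, None, :] - centroids[None, :, :], axis=2)
        new_labels = np.argmin(dists, axis=1)
        new_centroids = centroids.copy()
        for c in range(k):
            mask = new_labels == c
            if mask.any():
                new_centroids[c] = pts[mask].mean(axis=0)
        shift = np.linalg.norm(new_centroids - centroids, axis=1).max()
        converged = np.array_equal(new_labels, labels) and shift <= tol
        labels, centroids = new_labels, new_centroids
        if converged:
            break
    for c in range(k):
        if not (labels == c).any():
            logger.warning("k-means cluster %d is empty at convergence", c)
    return labels, centroids


def assign_trait_groups(
    scaled: pd.DataFrame,
    initial_centroids: Sequence[Sequence[float]] = DEFAULT_CENTROIDS,
) -> np.ndarray:
    """Cluster species on scaled (drought, shade) coordinates.

    ``scaled`` needs columns ``drought_scaled`` and ``shade_scaled``; returns
    an integer cluster label per row.
    """
    pts = scaled[["drought_scaled", "shade_scaled"]].to_numpy(dtype=float)
    labels, _ = lloyd_kmeans(pts, np.asarray(initial_centroids, dtype=float))
    return labels


def label_groups(
    cluster_labels: np.ndarray, traits: pd.DataFrame
) -> dict[int, str]:
    """Map cluster index -> ``D<d>S<s>`` label from member trait means.

    The drought and shade digits are the rounded cluster means on the
    original 1-5 scale; colliding codes get an ``a``, ``b``, ... suffix in
    cluster-index order.
    """
    codes: dict[int, str] = {}
    for c in sorted(set(int(c) for c in cluster_labels)):
        mask = cluster_labels == c
        d = int(round(traits.loc[mask, "drought_tol"].mean()))
        s = int(round(traits.loc[mask, "shade_tol"].mean()))
        codes[c] = f"D{d}S{s}"
    counts: dict[str, list[int]] = {}
    for c, code in codes.items():
        counts.setdefault(code, []).append(c)
    for code, clusters in counts.items():
        if len(clusters) > 1:
            for i, c in enumerate(clusters):
                codes[c] = f"{code}{chr(ord('a') + i)}"
    return codes


def genus_fallback(traits: pd.DataFrame) -> pd.DataFrame:
    """Fill missing species-level traits with congeneric means.

    Rows missing shade_tol, drought_tol or sca get the mean over species of
    the same genus that do have the value.  Raises if a genus has no donor
    for a needed trait.
    """
    out = traits.copy()
    for col in ("shade_tol", "drought_tol", "sca"):
        if col not in out.columns:
            continue
        genus_mean = out.groupby("genus")[col].mean()
        missing = out[col].isna()
        for idx in out.index[missing]:
            genus = out.at[idx, "genus"]
            value = genus_mean.get(genus, np.nan)
            if pd.isna(value):
                raise ValueError(
                    f"no {col} value available for species "
                    f"{out.at[idx, 'species']!r} (genus {genus!r} has no donors)"
                )
            out.at[idx, col] = value
    return out


def group_species(
    traits: pd.DataFrame,
    initial_centroids: Sequence[Sequence[float]] = DEFAULT_CENTROIDS,
) -> tuple[pd.DataFrame, list[TraitGroup]]:
    """End-to-end grouping: fallback, scale, cluster, label.

    Parameters
    ----------
    traits : DataFrame
        Columns species, genus, shade_tol, drought_tol (sca optional).

    Returns
    -------
    (assignments, groups)
        ``assignments`` is the completed trait table with added columns
        drought_scaled, shade_scaled, group_label; ``groups`` is the list of
        :class:`TraitGroup`.
    """
    table = genus_fallback(traits).reset_index(drop=True)
    table["drought_scaled"] = scale_traits(table["drought_tol"])
    table["shade_scaled"] = scale_traits(table["shade_tol"])
    labels = assign_trait_groups(table, initial_centroids)
    codes = label_groups(labels, table)
    table["group_label"] = [codes[int(c)] for c in labels]
    groups = []
    for c, code in codes.items():
        mask = labels == c
        members = frozenset(table.loc[mask, "species"])
        if mask.any():
            centroid = (
                float(table.loc[mask, "drought_scaled"].mean()),
                float(table.loc[mask, "shade_scaled"].mean()),
            )
        else:
            centroid = (float("nan"), float("nan"))
        groups.append(TraitGroup(label=code, members=members, centroid=centroid))
    return table, groups
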