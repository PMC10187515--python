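"""Presence and background point simulation.

Presences are simulated uniformly over the raster cells intersected by the
species range polygons, one point per cell at most (cell-uniqueness keeps
the presence sample from over-weighting any cell during model fitting).
Background points are drawn, again one per cell, inside the region formed by
the ecoregions that intersect the range polygons united with the prey
polygon, with cell probability inversely proportional to the distance to
the nearest presence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from shapely import contains_xy, union_all
from shapely.geometry.base import BaseGeometry

from .grids import GridRaster
from .synthio import RegionSet

__all__ = [
    "OccurrenceSet",
    "BackgroundSet",
    "DEFAULT_N_OCCURRENCES",
    "DEFAULT_N_BACKGROUND",
    "simulate_occurrences",
    "build_background_region",
    "simulate_background",
]

#: Default presence count — one simulated point per mature individual in the
#: most recent census estimate (197), rounded to 200.
DEFAULT_N_OCCURRENCES = 200

#: Default background sample size (capped by half the eligible cells on
#: small grids; see :func:`simulate_background`).
DEFAULT_N_BACKGROUND = 10_000


@dataclass
class OccurrenceSet:
    """Simulated presences: point coordinates, their cells, and the id of
    the range polygon each point fell in."""

    points: np.ndarray  # (n, 2) x, y
    cell_index: np.ndarray  # (n, 2) row, col
    source_polygon: np.ndarray  # (n,) int

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BackgroundSet:
    """Background sample: coordinates, cells and the (unnormalized)
    inverse-distance sampling weight of each drawn cell."""

    points: np.ndarray
    cell_index: np.ndarray
    sampling_weight: np.ndarray

    def __len__(self) -> int:
        return len(self.points)


def _cells_in_polygons(grid: GridRaster, polygons: list[BaseGeometry]):
    """(rows, cols, xs, ys, polygon_id) of non-missing cells whose centers
    fall inside any polygon (first containing polygon wins)."""
    xs, ys = grid.cell_centers()
    flat_x, flat_y = xs.ravel(), ys.ravel()
    poly_id = np.full(flat_x.shape, -1, dtype=int)
    for i, poly in enumerate(polygons):
        undecided = poly_id < 0
        if not undecided.any():
            break
        inside = contains_xy(poly, flat_x[undecided], flat_y[undecided])
        idx = np.flatnonzero(undecided)[inside]
        poly_id[idx] = i
    eligible = (poly_id >= 0) & ~grid.missing_mask.ravel()
    idx = np.flatnonzero(eligible)
    rows, cols = np.unravel_index(idx, grid.shape)
    return rows, cols, flat_x[idx], flat_y[idx], poly_id[idx]


def simulate_occurrences(
    regions: RegionSet,
    grid: GridRaster,
    n: int = DEFAULT_N_OCCURRENCES,
    seed: int = 0,
) -> OccurrenceSet:
    """Draw ``n`` presence points uniformly over the cells intersecting the
    species polygons, without replacement (at most one point per cell).

    Points are placed at cell centers: with the one-per-cell constraint the
    sub-cell position carries no information for the model.

    Raises
    ------
    ValueError
        If ``n`` exceeds the number of eligible cells.
    """
    rows, cols, xs, ys, poly_id = _cells_in_polygons(grid, regions.species_polygons)
    if n > len(rows):
        raise ValueError(
            f"requested {n} occurrences but only {len(rows)} grid cells intersect "
            "the species polygons"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False)
    return OccurrenceSet(
        points=np.column_stack([xs[pick], ys[pick]]),
        cell_index=np.column_stack([rows[pick], cols[pick]]),
        source_polygon=poly_id[pick],
    )


def build_background_region(regions: RegionSet) -> BaseGeometry:
    """Union of the ecoregions intersecting any species polygon with the
    prey polygon — the territory that could plausibly host the species.

    If no ecoregion intersects the range polygons a warning is issued and
    the prey polygon alone is returned.
    """
    hits = [
        eco
        for eco in regions.ecoregion_polygons
        if any(eco.intersects(sp) for sp in regions.species_polygons)
    ]
    if not hits:
        warnings.warn(
            "no ecoregion intersects the species polygons; background region "
            "falls back to the prey polygon alone",
            stacklevel=2,
        )
        return regions.prey_polygon
    return union_all(hits + [regions.prey_polygon])


def simulate_background(
    region: BaseGeometry,
    occ: OccurrenceSet,
    grid: GridRaster,
    n: int = DEFAULT_N_BACKGROUND,
    seed: int = 0,
) -> BackgroundSet:
    """Draw background points over the cells of ``region``, one per cell,
    with probability inversely proportional to the distance to the nearest
    presence point.

    The weight is ``1 / (d + eps)`` with ``eps`` equal to one cell size,
    which keeps the weight finite at cells that contain a presence.  On
    grids with fewer than ``2 n`` eligible cells the sample size is scaled
    down to half the eligible cells (a warning reports the actual size).
    """
    if len(occ) == 0:
        raise ValueError("background simulation requires a non-empty occurrence set")
    rows, cols, xs, ys, _ = _cells_in_polygons(grid, [region])
    if len(rows) == 0:
        raise ValueError("background region contains no grid cells")
    n_eff = min(n, len(rows) // 2) if len(rows) < 2 * n else n
    n_eff = max(n_eff, 1)
    if n_eff < n:
        warnings.warn(
            f"background sample scaled down to {n_eff} points "
            f"({len(rows)} eligible cells)",
            stacklevel=2,
        )
    tree = cKDTree(occ.points)
    d, _ = tree.query(np.column_stack([xs, ys]))
    w = 1.0 / (d + grid.cell_size)
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n_eff, replace=False, p=p)
    return BackgroundSet(
        points=np.column_stack([xs[pick], ys[pick]]),
        cell_index=np.column_stack([rows[pick], cols[pick]]),
        sampling_weight=w[pick],
    )
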