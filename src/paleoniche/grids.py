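"""Core raster containers.

All spatial computation in this package works on abstract equal-area grids:
a cell of side ``cell_size`` has area ``cell_size ** 2``, and areas are cell
counts times cell area.  No map projection math is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

__all__ = ["GridRaster", "ClimateStack", "ClimateSeries", "HINDCAST_LAYERS"]

#: Layer set carried by every hindcast (past) stack: mean temperature of the
#: warmest / coldest quarter, precipitation of the warmest / coldest quarter,
#: and net primary productivity.
HINDCAST_LAYERS = ("BIO10", "BIO11", "BIO18", "BIO19", "NPP")


@dataclass
class GridRaster:
    """A rectangular single-band raster on an abstract equal-area grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; row 0 is the southernmost row (origin is the lower-left
        corner of the grid).
    cell_size : float
        Side length of a (square) cell in abstract length units.
    origin : (float, float)
        ``(x, y)`` of the lower-left corner of the grid.
    missing_mask : ndarray of bool, optional
        True where the cell carries no data.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask shape must match values")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return int(self.values.size)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` arrays (each shape (nrows, ncols)) of cell centers."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncols) + 0.5) * self.cell_size
        ys = y0 + (np.arange(nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 + (row + 0.5) * self.cell_size)

    def valid_values(self) -> np.ndarray:
        """Values of non-missing cells, flattened."""
        return self.values[~self.missing_mask]

    def copy_with(self, values: np.ndarray) -> "GridRaster":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class ClimateStack:
    """Named environmental layers sharing one grid at one time/scenario.

    ``time_label`` is kilo-years before present for past stacks (0 = present)
    or a calendar year for future stacks; ``scenario`` identifies a future
    (emulator, ssp) pair and is None otherwise.
    """

    layers: dict[str, GridRaster]
    time_label: float = 0.0
    scenario: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        shapes = {lyr.shape for lyr in self.layers.values()}
        sizes = {lyr.cell_size for lyr in self.layers.values()}
        if len(shapes) > 1 or len(sizes) > 1:
            raise ValueError("all layers in a stack must share grid geometry")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> GridRaster:
        """Any layer's raster, exposing the shared geometry."""
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> GridRaster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def to_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Stack layers into an (n_cells, n_layers) matrix (row-major cells)."""
        names = list(self.layers) if names is None else names
        return np.column_stack([self.layers[n].values.ravel() for n in names])

    def subset(self, names: list[str]) -> "ClimateStack":
        return ClimateStack(
            {n: self.layers[n] for n in names},
            time_label=self.time_label,
            scenario=self.scenario,
        )

    def map_layers(self, func) -> "ClimateStack":
        """Apply ``func(name, GridRaster) -> GridRaster`` to every layer."""
        return ClimateStack(
            {n: func(n, lyr) for n, lyr in self.layers.items()},
            time_label=self.time_label,
            scenario=self.scenario,
        )


@dataclass
class ClimateSeries:
    """The full climate input set: past series, present (fine + coarse), futures.

    ``past`` is ordered oldest-to-youngest or youngest-to-oldest but with a
    constant step in ka; ``present_coarse`` shares its grid with the past
    stacks so hindcast projections are comparable with the present.
    ``future`` maps (emulator, ssp, period_year) to a stack on the fine grid.
    """

    past: list[ClimateStack]
    present_fine: ClimateStack
    present_coarse: ClimateStack
    future: dict[tuple[str, str, int], ClimateStack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [s.time_label for s in self.past]
        if len(times) >= 2:
            steps = np.diff(times)
            if not np.allclose(steps, steps[0]) or steps[0] == 0:
                raise ValueError("past stacks must be strictly ordered with constant step")
        coarse_shape = self.present_coarse.grid.shape
        for s in self.past:
            if s.grid.shape != coarse_shape:
                raise ValueError("present_coarse must share its grid with past stacks")

    @property
    def past_times(self) -> np.ndarray:
        return np.array([s.time_label for s in self.past])

    def iter_future(self) -> Iterator[tuple[tuple[str, str, int], ClimateStack]]:
        return iter(self.future.items())
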