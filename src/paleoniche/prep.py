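"""Variable pre-processing.

Four standard steps sit between the raw climate layers and the niche model:

* a standardized (correlation-matrix) principal-component transform of the
  five hindcast layers, fitted on the present and re-applied to every past
  stack, collapsing their collinearity into orthogonal scores;
* an iterative variance-inflation-factor filter (threshold 3) for the
  forecasting variable set;
* a multivariate environmental similarity surface (MESS), flagging
  projection cells whose variable combinations fall outside the calibration
  range (negative similarity = extrapolation), plus the screening rule that
  drops a variable whose mean out-of-range proportion across time bins
  exceeds a cutoff (default 20 %);
* block-mean raster aggregation for resolution matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import ClimateStack, GridRaster

__all__ = [
    "PCATransform",
    "MESSMap",
    "fit_pca",
    "vif_filter",
    "mess",
    "screen_variables_by_mess",
    "aggregate_raster",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCATransform:
    """Standardized PCA fitted on the non-missing cells of a present stack."""

    layer_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray  # (n_layers, n_components), orthonormal columns
    eigenvalues: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def score_names(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.n_components)]

    def transform_matrix(self, X: np.ndarray) -> np.ndarray:
        """Scores for an (n, n_layers) matrix in ``layer_names`` order."""
        Z = (np.asarray(X, dtype=float) - self.means) / self.scales
        return Z @ self.loadings

    def transform(self, stack: ClimateStack) -> ClimateStack:
        """Project a stack with the fitted loadings into PC-score layers."""
        missing = [n for n in self.layer_names if n not in stack]
        if missing:
            raise KeyError(f"stack lacks layers required by the PCA: {missing}")
        grid = stack.grid
        X = stack.to_matrix(self.layer_names)
        S = self.transform_matrix(X)
        mask = np.zeros(grid.shape, dtype=bool)
        for n in self.layer_names:
            mask |= stack[n].missing_mask
        layers = {}
        for i, name in enumerate(self.score_names):
            vals = S[:, i].reshape(grid.shape)
            layers[name] = GridRaster(
                vals, cell_size=grid.cell_size, origin=grid.origin, missing_mask=mask
            )
        return ClimateStack(layers, time_label=stack.time_label, scenario=stack.scenario)

    def inverse_transform_matrix(self, scores: np.ndarray) -> np.ndarray:
        return (scores @ self.loadings.T) * self.scales + self.means


def fit_pca(present_stack: ClimateStack, layer_names: list[str] | None = None) -> PCATransform:
    """Fit a correlation-matrix PCA on the non-missing cells of a stack.

    All components are kept (the transform is a rotation, not a reduction).
    Each loading column is oriented so its largest-magnitude entry is
    positive.  A constant layer gets a guarded unit scale and a warning.
    """
    names = present_stack.layer_names if layer_names is None else layer_names
    if len(names) < 2:
        raise ValueError("PCA requires at least two layers")
    mask = np.zeros(present_stack.grid.shape, dtype=bool)
    for n in names:
        mask |= present_stack[n].missing_mask
    X = np.column_stack([present_stack[n].values[~mask] for n in names])
    if X.shape[0] < len(names):
        raise ValueError("fewer non-missing cells than layers")
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    const = scales == 0
    if const.any():
        warnings.warn(
            f"constant layer(s) {list(np.array(names)[const])}: scale guarded to 1",
            stacklevel=2,
        )
        scales = np.where(const, 1.0, scales)
    Z = (X - means) / scales
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # sign convention: largest-|loading| entry of each column positive
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return PCATransform(
        layer_names=list(names),
        means=means,
        scales=scales,
        loadings=eigvec,
        eigenvalues=np.clip(eigval, 0.0, None),
    )


# ---------------------------------------------------------------------------
# VIF filter
# ---------------------------------------------------------------------------

def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j regressed on the others: 1 / (1 - R^2)."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return 1.0
    r2 = 1.0 - resid @ resid / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_filter(
    stack: ClimateStack,
    threshold: float = 3.0,
    layer_names: list[str] | None = None,
) -> list[str]:
    """Iteratively drop the layer with the largest VIF while any exceeds
    ``threshold``; return the retained layer names.

    Removal is worst-first, ties broken by layer-name order, so the result
    is deterministic.  Stops with a warning if fewer than two layers remain.
    """
    names = list(present_names(stack) if layer_names is None else layer_names)
    if len(names) < 2:
        raise ValueError("VIF filtering requires at least two layers")
    mask = np.zeros(stack.grid.shape, dtype=bool)
    for n in names:
        mask |= stack[n].missing_mask
    data = {n: stack[n].values[~mask] for n in names}
    while True:
        X = np.column_stack([data[n] for n in names])
        vifs = np.array([_vif_one(X, j) for j in range(len(names))])
        if np.all(vifs <= threshold):
            break
        worst = int(np.argmax(vifs))  # argmax takes the first of tied maxima
        names.pop(worst)
        if len(names) < 2:
            warnings.warn("VIF filter stopped: fewer than two layers remain", stacklevel=2)
            break
    return names


def present_names(stack: ClimateStack) -> list[str]:
    return stack.layer_names


# ---------------------------------------------------------------------------
# MESS
# ---------------------------------------------------------------------------

@dataclass
class MESSMap:
    """Per-cell minimum similarity and the per-variable similarity grids."""

    minimum: GridRaster
    per_variable: dict[str, GridRaster]

    def out_of_range_fraction(self, variable: str) -> float:
        """Fraction of non-missing cells where ``variable`` is outside the
        reference min-max (negative similarity)."""
        g = self.per_variable[variable]
        vals = g.valid_values()
        return float(np.mean(vals < 0)) if vals.size else 0.0


def _mess_similarity(ref: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Standard per-variable MESS similarity.

    With ``f`` the percentage of reference values below the target value:
    ``f = 0`` -> linearly negative below the reference minimum;
    ``f <= 50`` -> ``2 f``; ``f < 100`` -> ``2 (100 - f)``;
    ``f = 100`` -> linearly negative above the reference maximum.
    Similarity is 100 at the reference median and negative exactly when the
    value lies outside the reference min-max.
    """
    ref = np.sort(np.asarray(ref, dtype=float))
    if ref.size == 0:
        raise ValueError("empty reference sample")
    lo, hi = ref[0], ref[-1]
    span = hi - lo if hi > lo else 1.0
    f = 100.0 * np.searchsorted(ref, values, side="left") / ref.size
    sim = np.where(f <= 50.0, 2.0 * f, 2.0 * (100.0 - f))
    sim = np.where(values < lo, (values - lo) / span * 100.0, sim)
    sim = np.where(values > hi, (hi - values) / span * 100.0, sim)
    return sim


def mess(reference_values: dict[str, np.ndarray], target_stack: ClimateStack) -> MESSMap:
    """MESS of a projection stack against per-variable reference samples.

    The reference sample is normally the variable values at the calibration
    points (presences + background); the per-cell map value is the minimum
    similarity across variables.
    """
    grid = target_stack.grid
    per_var: dict[str, GridRaster] = {}
    min_vals = np.full(grid.shape, np.inf)
    mask = np.zeros(grid.shape, dtype=bool)
    for name, ref in reference_values.items():
        layer = target_stack[name]
        sim = _mess_similarity(ref, layer.values)
        per_var[name] = GridRaster(
            sim, cell_size=grid.cell_size, origin=grid.origin, missing_mask=layer.missing_mask
        )
        min_vals = np.minimum(min_vals, sim)
        mask |= layer.missing_mask
    return MESSMap(
        minimum=GridRaster(min_vals, cell_size=grid.cell_size, origin=grid.origin, missing_mask=mask),
        per_variable=per_var,
    )


def screen_variables_by_mess(
    mess_maps: list[MESSMap], cutoff: float = 0.20
) -> list[str]:
    """Retain variables whose mean out-of-range cell proportion across time
    bins does not exceed ``cutoff``."""
    if not mess_maps:
        raise ValueError("at least one MESS map is required")
    names = list(mess_maps[0].per_variable)
    retained = []
    for name in names:
        props = [m.out_of_range_fraction(name) for m in mess_maps]
        if float(np.mean(props)) <= cutoff:
            retained.append(name)
    return retained


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_raster(raster: GridRaster, factor: int) -> GridRaster:
    """Block-mean aggregation by an integer factor, ignoring missing cells.

    Edge blocks (when the grid is not a multiple of ``factor``) use the mean
    of their available cells.  Output cell size is ``factor`` times the
    input's; a block with no valid cell is marked missing.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    nr, nc = raster.shape
    if factor > max(nr, nc):
        raise ValueError("aggregation factor exceeds the grid size")
    if factor == 1:
        return GridRaster(
            raster.values.copy(),
            cell_size=raster.cell_size,
            origin=raster.origin,
            missing_mask=raster.missing_mask.copy(),
        )
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    vals = np.full((out_r, out_c), np.nan)
    miss = np.ones((out_r, out_c), dtype=bool)
    v = np.where(raster.missing_mask, np.nan, raster.values)
    for i in range(out_r):
        for j in range(out_c):
            block = v[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
            if np.isfinite(block).any():
                vals[i, j] = np.nanmean(block)
                miss[i, j] = False
    return GridRaster(
        np.where(miss, 0.0, vals),
        cell_size=raster.cell_size * factor,
        origin=raster.origin,
        missing_mask=miss,
    )
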