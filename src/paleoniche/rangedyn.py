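"""Temporal range reconstruction and its statistics.

A habitat-suitability map per time bin is binarized into a geographic range
with a single threshold chosen by the *minimum useful threshold* (MUT)
strategy: scan the candidate grid 0.01..1 (step 0.01) and keep the largest
threshold at which every time bin still retains at least one in-range cell,
so no bin ever yields a null range while the range stays as restrictive as
possible.  Within-range cells are split at HSI 0.5 into good-to-best (GB,
HSI > 0.5) and good-to-worst (GW, HSI <= 0.5) habitat.  Per-bin conditions
are compared with the present by rank-sum tests; range-area variance across
bin groups is compared with the Brown-Forsythe test; and the relationship
between range area and temperature / altitude is estimated by regression
with ARIMA errors selected by AIC (plain OLS is retained when its residuals
show no significant autocorrelation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.ar_model import ar_select_order
from statsmodels.tsa.statespace.sarimax import SARIMAX
import statsmodels.api as sm

from .grids import GridRaster

__all__ = [
    "ThresholdResult",
    "RangeSeries",
    "TrendModel",
    "TrendFit",
    "compute_mut",
    "binarize_range",
    "gb_gw_split",
    "compare_bin_to_present",
    "brown_forsythe",
    "build_range_series",
]

DEFAULT_THRESHOLDS = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)


@dataclass
class ThresholdResult:
    mut: float
    grid: np.ndarray
    #: nonzero[i, b] — does bin b keep >= 1 cell at grid threshold i?
    nonzero: np.ndarray


def compute_mut(
    hsi_maps: list[GridRaster], grid: np.ndarray | None = None
) -> ThresholdResult:
    """Minimum useful threshold over a series of suitability maps.

    The MUT is the largest candidate threshold t such that, for every time
    bin, at least one non-missing cell has HSI >= t.  Raises if even the
    smallest candidate nullifies some bin (the offending bin is named).
    """
    if not hsi_maps:
        raise ValueError("at least one suitability map is required")
    grid = DEFAULT_THRESHOLDS if grid is None else np.asarray(grid, dtype=float)
    maxes = np.array([m.valid_values().max() for m in hsi_maps])
    nonzero = maxes[None, :] >= grid[:, None]
    feasible = nonzero.all(axis=1)
    if not feasible.any():
        worst = int(np.argmin(maxes))
        raise ValueError(
            f"no candidate threshold keeps every bin non-null: bin {worst} has "
            f"max HSI {maxes[worst]:.4f} below the smallest candidate {grid[0]}"
        )
    mut = float(grid[feasible][-1]) if np.all(np.diff(grid) > 0) else float(grid[feasible].max())
    return ThresholdResult(mut=mut, grid=grid, nonzero=nonzero)


def binarize_range(hsi: GridRaster, t: float) -> tuple[np.ndarray, float]:
    """(mask of in-range cells, range area).

    A cell is in range when its HSI is >= t (cells equal to the threshold
    are kept); area = in-range cell count x cell area.
    """
    if not (0.0 < t <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    mask = (hsi.values >= t) & ~hsi.missing_mask
    return mask, float(mask.sum()) * hsi.cell_area


def gb_gw_split(hsi: GridRaster, mask: np.ndarray) -> tuple[float, float]:
    """Split the in-range area at HSI 0.5: (GB area, GW area).

    GB (good-to-best) cells have HSI strictly above 0.5; GW (good-to-worst)
    cells sit at or below 0.5 — a cell at exactly 0.5 counts as GW.
    """
    vals = hsi.values[mask]
    gb = float(np.sum(vals > 0.5)) * hsi.cell_area
    gw = float(np.sum(vals <= 0.5)) * hsi.cell_area
    return gb, gw


def compare_bin_to_present(
    bin_values: np.ndarray, present_values: np.ndarray, alpha: float = 0.05
) -> tuple[bool, bool, float]:
    """Rank-sum comparison of a past bin's in-range HSI sample with the
    present's.

    Returns ``(better, similar, p_two_sided)``: "better" means the one-sided
    greater test is significant at ``alpha``; "similar" means the two-sided
    test is not.  Exact enumeration is used for small tie-free samples,
    the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(bin_values, dtype=float)
    b = np.asarray(present_values, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return False, True, 1.0
    ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    p_two = stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    p_greater = stats.mannwhitneyu(a, b, alternative="greater", method=method).pvalue
    return bool(p_greater < alpha), bool(p_two >= alpha), float(p_two)


def brown_forsythe(*groups: np.ndarray) -> tuple[float, float]:
    """Brown-Forsythe equality-of-variance test.

    One-way ANOVA F on the absolute deviations from each group's median —
    the robust variance comparison used to contrast range-area variability
    between bins younger and older than the glacial-cycle switch.  Returns
    ``(statistic, p)``; the statistic is +inf when groups differ with zero
    within-group spread of the deviations, and an error is raised when the
    deviations carry no signal at all.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    gs = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 2 for g in gs):
        raise ValueError("each group needs at least two values")
    z = [np.abs(g - np.median(g)) for g in gs]
    zbar = [zi.mean() for zi in z]
    grand = np.concatenate(z).mean()
    between = sum(zi.size * (m - grand) ** 2 for zi, m in zip(z, zbar))
    within = sum(np.sum((zi - m) ** 2) for zi, m in zip(z, zbar))
    if between == 0 and within == 0:
        raise ValueError("Brown-Forsythe statistic undefined: no variation in deviations")
    if within == 0:
        return float("inf"), 0.0
    stat, p = stats.levene(*gs, center="median")
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# range series assembly
# ---------------------------------------------------------------------------

@dataclass
class RangeSeries:
    """Per-bin range statistics as a tidy table.

    Columns: time_ka, range_area, mean_hsi, mean_altitude, mean_temperature,
    gb_area, gw_area, better_flag, similar_flag, p_two_sided.
    """

    table: pd.DataFrame
    mut: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def build_range_series(
    hsi_maps: list[GridRaster],
    times_ka: np.ndarray,
    present_hsi: GridRaster,
    altitude: GridRaster | None = None,
    temperature_maps: list[GridRaster] | None = None,
    mut: float | None = None,
) -> RangeSeries:
    """Binarize every bin at the (optionally precomputed) MUT and assemble
    the per-bin area / HSI / altitude / temperature series plus the
    better/similar-than-present flags."""
    if mut is None:
        mut = compute_mut(hsi_maps).mut
    pres_mask, _ = binarize_range(present_hsi, mut)
    present_vals = present_hsi.values[pres_mask]
    rows = []
    for i, (hsi, t) in enumerate(zip(hsi_maps, times_ka)):
        mask, area = binarize_range(hsi, mut)
        vals = hsi.values[mask]
        gb, gw = gb_gw_split(hsi, mask)
        better, similar, p = compare_bin_to_present(vals, present_vals)
        row = {
            "time_ka": float(t),
            "range_area": area,
            "mean_hsi": float(vals.mean()) if vals.size else np.nan,
            "gb_area": gb,
            "gw_area": gw,
            "better_flag": better,
            "similar_flag": similar,
            "p_two_sided": p,
        }
        row["mean_altitude"] = (
            float(altitude.values[mask].mean()) if altitude is not None and mask.any() else np.nan
        )
        # territory-wide mean temperature (the climate forcing the range
        # responds to), not the within-range mean
        row["mean_temperature"] = (
            float(temperature_maps[i].valid_values().mean())
            if temperature_maps is not None
            else np.nan
        )
        rows.append(row)
    return RangeSeries(table=pd.DataFrame(rows), mut=float(mut))


# ---------------------------------------------------------------------------
# trend regression with ARIMA errors
# ---------------------------------------------------------------------------

@dataclass
class TrendFit:
    """Selected trend model: slope of the predictor, its p-value, the
    ARIMA-error orders and the AIC of the winning candidate."""

    family: str  # "OLS" or "ARIMA"
    order: tuple[int, int, int]
    slope: float
    slope_pvalue: float
    aic: float
    candidates: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"trend fit [{self.family} order={self.order}]  "
            f"slope={self.slope:.4f}  p={self.slope_pvalue:.3g}  AIC={self.aic:.1f}"
        )


class TrendModel:
    """Regression of a response series on a predictor series with
    autocorrelation-aware error selection.

    Strategy: fit OLS first and test its residuals for autocorrelation
    (Ljung-Box at lag min(10, n/5), alpha 0.05).  If uncorrelated, OLS is
    the final model.  Otherwise two candidate families are scanned and the
    minimum-AIC model wins: (1) regressions with ARIMA errors whose AR order
    comes from maximum-likelihood order selection on the OLS residuals,
    differencing d in {0, 1} and MA order 0..6; (2) a fully automatic
    order search over a small (p, d, q) grid.
    """

    def __init__(self, response: np.ndarray, predictor: np.ndarray) -> None:
        y = np.asarray(response, dtype=float)
        x = np.asarray(predictor, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("response and predictor must be equal-length 1-D series")
        if y.size < 20:
            raise ValueError("trend fitting needs at least 20 time bins")
        if not (np.isfinite(y).all() and np.isfinite(x).all()):
            raise ValueError("non-finite values in the series")
        self.y, self.x = y, x

    def fit(
        self,
        max_ma: int = 6,
        auto_grid: tuple[int, int, int] = (3, 1, 3),
        alpha: float = 0.05,
    ) -> TrendFit:
        y, x = self.y, self.x
        n = y.size
        X = sm.add_constant(x)
        ols = sm.OLS(y, X).fit()
        lags = max(1, min(10, n // 5))
        lb_p = float(acorr_ljungbox(ols.resid, lags=[lags]).iloc[0]["lb_pvalue"])
        candidates = [
            {"family": "OLS", "order": (0, 0, 0), "aic": float(ols.aic),
             "slope": float(ols.params[1]), "pvalue": float(ols.pvalues[1])}
        ]
        if lb_p >= alpha:
            c = candidates[0]
            return TrendFit("OLS", (0, 0, 0), c["slope"], c["pvalue"], c["aic"], candidates)

        # strategy 1: AR order from the OLS residuals, d in {0,1}, MA 0..max_ma
        try:
            sel = ar_select_order(ols.resid, maxlag=min(8, n // 10), ic="aic", old_names=False)
            p_res = len(sel.ar_lags) if sel.ar_lags is not None else 0
        except Exception:
            p_res = 1
        orders = {(p_res, d, q) for d in (0, 1) for q in range(0, max_ma + 1)}
        # strategy 2: automatic search over a small grid
        pmax, dmax, qmax = auto_grid
        orders |= {
            (p, d, q)
            for p in range(pmax + 1)
            for d in range(dmax + 1)
            for q in range(qmax + 1)
        }
        orders.discard((0, 0, 0))
        for order in sorted(orders):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = SARIMAX(
                        y, exog=x, order=order, trend="c" if order[1] == 0 else None
                    ).fit(disp=False, maxiter=200)
                candidates.append(
                    {"family": "ARIMA", "order": order, "aic": float(fit.aic),
                     "slope": float(fit.params[fit.param_names.index("x1")]),
                     "pvalue": float(fit.pvalues[fit.param_names.index("x1")])}
                )
            except Exception as err:  # non-invertible corner cases are skipped
                warnings.warn(f"ARIMA{order} failed: {err}", stacklevel=2)
        best = min(candidates, key=lambda c: c["aic"])
        return TrendFit(
            best["family"], tuple(best["order"]), best["slope"], best["pvalue"],
            best["aic"], candidates,
        )


def plot_range_series(series: RangeSeries, ax=None):
    """Quick look at the range-area trajectory (log10 area vs time)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = series.table["time_ka"]
    ax.plot(t, np.log10(series.table["range_area"].clip(lower=1e-12)), lw=1)
    ax.set_xlabel("time (ka before present)")
    ax.set_ylabel("log10 range area")
    ax.invert_xaxis()
    return ax
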