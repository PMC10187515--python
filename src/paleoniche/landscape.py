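"""Habitat-class maps, patch fragmentation metrics and scenario statistics.

Suitability maps are cut into four habitat classes (HSI < 0.25,
[0.25, 0.5), [0.5, 0.75), >= 0.75).  Per class the standard FRAGSTATS-style
patch metrics are computed on 4-neighbour (rook) connected components:

* ``np`` — number of patches; ``area_mn`` — mean patch area;
* ``ai`` — aggregation index: 100 x like-adjacencies / maximum possible
  like-adjacencies for the class area (single-count convention; the maximum
  for area A with n = floor(sqrt(A)), m = A - n^2 is 2n(n-1), +2m-1 if
  0 < m <= n, +2m-2 if m > n);
* ``clumpy`` — (G - P)/(1 - P) if G >= P else (G - P)/P, with G the
  proportion of like adjacencies among all adjacencies involving the class
  (double-count) and P the class's proportional abundance;
* ``cohesion`` — patch cohesion from patch perimeters and areas;
* ``division`` — probability that two random landscape cells fall in
  different patches of the class, 1 - sum (a_j / A_landscape)^2.

Scenario differences are tested with a two-way permutational MANOVA
(Euclidean distances, sequential sums of squares, permutations restricted
within strata), and temporal change in patch geometry with OLS / ordinal
regressions.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import ndimage

from .grids import GridRaster

__all__ = [
    "classify_hsi",
    "patch_metrics",
    "landscape_table",
    "prepare_landscape_response",
    "permanova_two_way",
    "patch_area_trend",
    "class_metric_glm",
    "CLASS_BOUNDS",
    "METRIC_NAMES",
]

CLASS_BOUNDS = (0.25, 0.5, 0.75)
METRIC_NAMES = ["np", "area_mn", "ai", "clumpy", "cohesion", "division"]

_ROOK = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
_QUEEN = np.ones((3, 3), dtype=int)


def classify_hsi(hsi: GridRaster) -> GridRaster:
    """Bin an HSI map into classes 1..4 (upper-open bins except class 4,
    which includes HSI = 1).  Missing cells stay missing (class 0)."""
    cls = np.digitize(hsi.values, CLASS_BOUNDS) + 1
    cls = np.where(hsi.missing_mask, 0, cls)
    return GridRaster(
        cls.astype(float), cell_size=hsi.cell_size, origin=hsi.origin,
        missing_mask=hsi.missing_mask,
    )


def _like_adjacencies(mask: np.ndarray) -> int:
    """Single-count like adjacencies (shared edges) within a boolean mask."""
    horiz = np.sum(mask[:, :-1] & mask[:, 1:])
    vert = np.sum(mask[:-1, :] & mask[1:, :])
    return int(horiz + vert)


def _max_like_adjacencies(area_cells: int) -> int:
    """Maximum single-count like adjacencies for a maximally compact class."""
    n = int(np.floor(np.sqrt(area_cells)))
    m = area_cells - n * n
    e = 2 * n * (n - 1)
    if m == 0:
        return e
    if m <= n:
        return e + 2 * m - 1
    return e + 2 * m - 2


def patch_metrics(
    cmap: GridRaster, class_id: int, eight_neighbour: bool = False
) -> dict[str, float]:
    """FRAGSTATS-style metrics for one class of a class map.

    Patches are 4-neighbour connected components by default (rook rule, the
    FRAGSTATS default; queen connectivity via ``eight_neighbour``).  An
    absent class yields ``np = 0`` and NaN for the other metrics.
    """
    valid = ~cmap.missing_mask
    if not valid.any():
        raise ValueError("empty landscape")
    mask = (cmap.values == class_id) & valid
    cell_area = cmap.cell_area
    out: dict[str, float] = {}
    a_cells = int(mask.sum())
    if a_cells == 0:
        return {"np": 0.0, "area_mn": np.nan, "ai": np.nan, "clumpy": np.nan,
                "cohesion": np.nan, "division": np.nan}
    labels, n_patches = ndimage.label(mask, structure=_QUEEN if eight_neighbour else _ROOK)
    out["np"] = float(n_patches)
    out["area_mn"] = a_cells * cell_area / n_patches

    # aggregation index
    e = _like_adjacencies(mask)
    max_e = _max_like_adjacencies(a_cells)
    out["ai"] = 100.0 * e / max_e if max_e > 0 else np.nan

    # clumpiness: like-adjacency proportion (double count) vs class abundance
    total_cells = int(valid.sum())
    P = a_cells / total_cells
    up = np.pad(mask, 1)[:-2, 1:-1] & mask
    down = np.pad(mask, 1)[2:, 1:-1] & mask
    left = np.pad(mask, 1)[1:-1, :-2] & mask
    right = np.pad(mask, 1)[1:-1, 2:] & mask
    g_like = int(up.sum() + down.sum() + left.sum() + right.sum())
    # all adjacencies involving the class (double count), landscape border excluded
    vpad = np.pad(valid, 1)
    g_all = 0
    for shift in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nb = np.roll(np.roll(vpad, shift[0], axis=0), shift[1], axis=1)[1:-1, 1:-1]
        g_all += int(np.sum(mask & nb))
    if g_all == 0:
        out["clumpy"] = np.nan
    else:
        G = g_like / g_all
        if P >= 1.0:
            out["clumpy"] = 1.0 if G == 1.0 else np.nan
        elif G >= P:
            out["clumpy"] = (G - P) / (1.0 - P)
        else:
            out["clumpy"] = (G - P) / P

    # cohesion
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_patches + 1))
    perims = np.empty(n_patches)
    for j in range(1, n_patches + 1):
        pm = labels == j
        perims[j - 1] = 4 * pm.sum() - 2 * _like_adjacencies(pm)
    Z = total_cells
    if Z > 1:
        num = perims.sum()
        den = np.sum(perims * np.sqrt(sizes))
        out["cohesion"] = 100.0 * (1.0 - num / den) / (1.0 - 1.0 / np.sqrt(Z))
    else:
        out["cohesion"] = np.nan

    # division (against the full landscape area, FRAGSTATS convention)
    out["division"] = 1.0 - float(np.sum((sizes / Z) ** 2))
    return out


def landscape_table(
    class_maps: dict[tuple[str, str, int], GridRaster],
    classes: tuple[int, ...] = (1, 2, 3, 4),
) -> pd.DataFrame:
    """One row per (emulator, ssp, period, class) with the patch metrics."""
    rows = []
    for (emu, ssp, period), cmap in class_maps.items():
        for c in classes:
            rec = patch_metrics(cmap, c)
            rec.update({"emulator": emu, "ssp": ssp, "period": period, "class": c})
            rows.append(rec)
    return pd.DataFrame(rows)


def prepare_landscape_response(
    table: pd.DataFrame,
    drop_class_1: bool = True,
    drop_zero_variance: bool = True,
    metrics: list[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """log10-transform the metric columns and apply the standard exclusions
    (drop the overabundant worst-HSI class 1; drop metrics with zero
    variance, typically ``division``).  Returns (kept rows, response
    matrix)."""
    metrics = [m for m in METRIC_NAMES if m != "division"] if metrics is None else metrics
    df = table.copy()
    if drop_class_1:
        df = df[df["class"] != 1]
    df = df.dropna(subset=metrics)
    cols = []
    kept = []
    for m in metrics:
        v = df[m].to_numpy(dtype=float)
        v = np.log10(np.clip(v, 1e-12, None)) if m != "clumpy" else v
        if drop_zero_variance and np.ptp(v) == 0:
            continue
        cols.append(v)
        kept.append(m)
    if not cols:
        raise ValueError("no metric with variance remains")
    return df.reset_index(drop=True), np.column_stack(cols)


# ---------------------------------------------------------------------------
# PerMANOVA
# ---------------------------------------------------------------------------

def _hat(X: np.ndarray) -> np.ndarray:
    return X @ np.linalg.pinv(X.T @ X) @ X.T


def _dummies(values: pd.Series) -> np.ndarray:
    return pd.get_dummies(values.astype("category"), drop_first=False).to_numpy(float)


def permanova_two_way(
    response: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    strata: np.ndarray | None = None,
    n_perm: int = 9999,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-way permutational MANOVA on Euclidean distances.

    Sequential (Type-I) sums of squares in the order (factor_a, factor_b);
    the residual comes from the additive two-factor model.  Permutations
    shuffle response rows, restricted within ``strata`` levels when given
    (repeated-measure stratification); ``p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm)``.  With a univariate response, one factor and free
    permutations the pseudo-F equals the classical one-way ANOVA F.
    """
    Y = np.atleast_2d(np.asarray(response, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    n = Y.shape[0]
    fa = pd.Series(np.asarray(factor_a))
    fb = pd.Series(np.asarray(factor_b))
    for name, f in (("factor_a", fa), ("factor_b", fb)):
        if f.value_counts().min() < 1 or f.nunique() < 2:
            raise ValueError(f"{name} needs >= 2 levels, each with >= 1 record")
    Yc = Y - Y.mean(axis=0)

    ones = np.ones((n, 1))
    Xa = np.column_stack([ones, _dummies(fa)])
    Xab = np.column_stack([ones, _dummies(fa), _dummies(fb)])
    H0, Ha, Hab = _hat(ones), _hat(Xa), _hat(Xab)
    df_a, df_b = fa.nunique() - 1, fb.nunique() - 1
    df_res = n - 1 - df_a - df_b

    def stats_for(Ym: np.ndarray) -> tuple[float, float]:
        ss_a = np.sum((Ha - H0) @ Ym * Ym)
        ss_b = np.sum((Hab - Ha) @ Ym * Ym)
        ss_res = np.sum((np.eye(n) - Hab) @ Ym * Ym)
        ms_res = ss_res / df_res if df_res > 0 else np.nan
        fa_ = (ss_a / df_a) / ms_res if ms_res > 0 else 0.0
        fb_ = (ss_b / df_b) / ms_res if ms_res > 0 else 0.0
        return fa_, fb_

    f_a, f_b = stats_for(Yc)
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    if strata is not None:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in pd.unique(strata)]
    count_a = count_b = 0
    for _ in range(n_perm):
        perm = idx.copy()
        if strata is None:
            rng.shuffle(perm)
        else:
            for g in groups:
                perm[g] = rng.permutation(perm[g])
        pa, pb = stats_for(Yc[perm])
        count_a += pa >= f_a
        count_b += pb >= f_b
    return pd.DataFrame(
        {
            "term": ["factor_a", "factor_b"],
            "df": [df_a, df_b],
            "pseudo_F": [f_a, f_b],
            "p": [(1 + count_a) / (1 + n_perm), (1 + count_b) / (1 + n_perm)],
        }
    )


def pairwise_permanova(
    response: np.ndarray,
    factor: np.ndarray,
    strata: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Pairwise follow-up: one-way permutational tests for every level pair
    of a significant factor (same machinery, second factor held constant)."""
    f = np.asarray(factor)
    Y = np.atleast_2d(np.asarray(response, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(pd.unique(f), 2):
        sel = (f == a) | (f == b)
        Ys = Y[sel] - Y[sel].mean(axis=0)
        fs = pd.Series(f[sel])
        n = Ys.shape[0]
        ones = np.ones((n, 1))
        H0, Ha = _hat(ones), _hat(np.column_stack([ones, _dummies(fs)]))
        df_a, df_res = fs.nunique() - 1, n - fs.nunique()

        def one_way_f(Ym: np.ndarray) -> float:
            ss_a = np.sum((Ha - H0) @ Ym * Ym)
            ss_res = np.sum((np.eye(n) - Ha) @ Ym * Ym)
            return (ss_a / df_a) / (ss_res / df_res) if ss_res > 0 else 0.0

        f_obs = one_way_f(Ys)
        sub_strata = strata[sel] if strata is not None else None
        groups = (
            [np.flatnonzero(sub_strata == s) for s in pd.unique(sub_strata)]
            if sub_strata is not None
            else None
        )
        idx = np.arange(n)
        count = 0
        for _ in range(n_perm):
            perm = idx.copy()
            if groups is None:
                rng.shuffle(perm)
            else:
                for g in groups:
                    perm[g] = rng.permutation(perm[g])
            count += one_way_f(Ys[perm]) >= f_obs
        rows.append(
            {"pair": f"{a} vs {b}", "pseudo_F": f_obs, "p": (1 + count) / (1 + n_perm)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def patch_area_trend(table: pd.DataFrame) -> dict[str, object]:
    """Per-emulator OLS of log10 mean patch area on period and habitat
    class (categorical).  Zero-area rows are dropped with a warning."""
    out = {}
    for emu, sub in table.groupby("emulator"):
        sub = sub.dropna(subset=["area_mn"])
        zero = sub["area_mn"] <= 0
        if zero.any():
            warnings.warn(f"{emu}: dropping {int(zero.sum())} zero-area rows", stacklevel=2)
            sub = sub[~zero]
        if sub["period"].nunique() < 2:
            raise ValueError("patch-area trend needs at least two periods")
        sub = sub.assign(log_area=np.log10(sub["area_mn"]))
        out[emu] = smf.ols("log_area ~ period + C(Q('class'))", data=sub).fit()
    return out


def class_metric_glm(table: pd.DataFrame, metrics: list[str] | None = None) -> dict[str, object]:
    """Per-emulator ordinal (proportional-odds) regression of the habitat
    class on the landscape metrics, each interacting with period.

    Falls back to an L2-penalized multinomial logit with a warning when the
    ordinal likelihood cannot be maximized (e.g. perfect separation)."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    metrics = ["np", "area_mn", "ai", "clumpy", "cohesion"] if metrics is None else metrics
    out = {}
    for emu, sub in table.groupby("emulator"):
        sub = sub.dropna(subset=metrics).copy()
        period_c = sub["period"] - sub["period"].mean()
        Xcols = {}
        for m in metrics:
            v = sub[m].to_numpy(float)
            v = (v - v.mean()) / (v.std() if v.std() > 0 else 1.0)
            Xcols[m] = v
            Xcols[f"{m}:period"] = v * period_c.to_numpy(float)
        X = pd.DataFrame(Xcols, index=sub.index)
        X = X.loc[:, X.std() > 0]
        y = sub["class"].astype(int)
        if y.nunique() < 2:
            raise ValueError("need at least two habitat classes present")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mod = OrderedModel(y, X, distr="logit")
                out[emu] = mod.fit(method="bfgs", maxiter=300, disp=False)
        except Exception as err:
            warnings.warn(f"{emu}: ordinal fit failed ({err}); penalized multinomial fallback",
                          stacklevel=2)
            mn = sm.MNLogit(pd.get_dummies(y).to_numpy(float), sm.add_constant(X))
            out[emu] = mn.fit_regularized(alpha=1.0, disp=False)
    return out
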