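"""Ensemble of small models.

Instead of one model on all predictors, every combination of a fixed-size
variable subset gets its own Maxent model (five 4-of-5 models for the
hindcast variable set, twenty-eight 6-of-8 models for the forecast set).
Each member is tuned by spatial-block cross-validation — occurrences are
grouped into spatially separated folds (by source range polygon when enough
polygons exist, otherwise by clustering coordinates) and the
feature-class x regularization grid point with the best mean held-out AUC
wins.  Member predictions are averaged with accuracy weights
``max(0, 2 (AUC - 0.5))`` (Somers' D floored at zero), normalized to sum
to one.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .grids import ClimateStack, GridRaster
from .maxent import FeatureSpec, MaxentModel, MaxentResults, predict_logistic
from .points import OccurrenceSet

__all__ = [
    "FoldAssignment",
    "SmallModel",
    "SmallModelEnsemble",
    "enumerate_subsets",
    "assign_spatial_folds",
    "auc",
    "tune_and_fit",
    "ensemble_predict",
    "DEFAULT_FEATURE_CLASSES",
    "DEFAULT_REG_MULTIPLIERS",
]

DEFAULT_FEATURE_CLASSES = ("L", "LQ", "LQH", "H")
DEFAULT_REG_MULTIPLIERS = (0.5, 1.0, 2.0, 4.0)


def enumerate_subsets(variables: list[str], subset_size: int) -> list[tuple[str, ...]]:
    """All size-``subset_size`` combinations in lexicographic (input) order."""
    if subset_size > len(variables):
        raise ValueError("subset_size exceeds the number of variables")
    return list(itertools.combinations(variables, subset_size))


@dataclass
class FoldAssignment:
    """Fold id (0..k-1) per occurrence and a descriptor of the method used."""

    fold: np.ndarray
    k: int
    method: str

    def __post_init__(self) -> None:
        counts = np.bincount(self.fold, minlength=self.k)
        if (counts == 0).any():
            raise ValueError("every fold must be non-empty")


def assign_spatial_folds(occ: OccurrenceSet, k: int = 12, seed: int = 0) -> FoldAssignment:
    """Spatially separated cross-validation folds.

    When the occurrences come from at least ``k`` distinct source polygons,
    folds follow the polygons (polygons are merged down to ``k`` groups by
    clustering their centroids when there are more).  Otherwise the point
    coordinates themselves are clustered into ``k`` spatially contiguous
    groups.
    """
    n = len(occ)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} occurrences")
    poly_ids = np.unique(occ.source_polygon)
    if len(poly_ids) >= k:
        if len(poly_ids) == k:
            remap = {p: i for i, p in enumerate(poly_ids)}
            fold = np.array([remap[p] for p in occ.source_polygon])
            return FoldAssignment(fold=fold, k=k, method="source-polygon")
        # merge polygons into k spatial groups via their occurrence centroids
        cents = np.array(
            [occ.points[occ.source_polygon == p].mean(axis=0) for p in poly_ids]
        )
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(cents)
        remap = {p: int(lbl) for p, lbl in zip(poly_ids, km.labels_)}
        fold = np.array([remap[p] for p in occ.source_polygon])
        return FoldAssignment(fold=fold, k=k, method="merged-polygons")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(occ.points)
    return FoldAssignment(fold=km.labels_.astype(int), k=k, method="coordinate-clusters")


def auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Probability that a random presence outscores a random background
    point, ties counted one half (the Mann-Whitney form of the AUC)."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("AUC requires non-empty score sets")
    ranks = rankdata(np.concatenate([sp, sb]))
    r_p = ranks[: sp.size].sum()
    u = r_p - sp.size * (sp.size + 1) / 2.0
    return float(u / (sp.size * sb.size))


@dataclass
class SmallModel:
    variables: tuple[str, ...]
    classes: str
    reg_multiplier: float
    cv_auc: float
    results: MaxentResults


@dataclass
class SmallModelEnsemble:
    members: list[SmallModel]
    weights: np.ndarray
    tuning_log: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["ensemble of small models", "-" * 60]
        for m, w in zip(self.members, self.weights):
            lines.append(
                f"{'+'.join(m.variables):<30s} fc={m.classes:<4s} "
                f"rm={m.reg_multiplier:<4g} cv_auc={m.cv_auc:.3f} w={w:.3f}"
            )
        return "\n".join(lines)


def tune_and_fit(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    variables: list[str],
    subset_size: int,
    folds: FoldAssignment,
    feature_classes: tuple[str, ...] = DEFAULT_FEATURE_CLASSES,
    reg_multipliers: tuple[float, ...] = DEFAULT_REG_MULTIPLIERS,
) -> SmallModelEnsemble:
    """Tune and fit one small model per variable subset, then weight by
    cross-validated accuracy.

    Per subset, every (feature classes, regularization multiplier) grid
    point is scored by leave-one-fold-out CV — held-out presences against
    the full background (the background is not folded) — and the best mean
    AUC wins (first grid point on ties).  The winner is refit on all data;
    the member weight is ``max(0, 2 (cv_auc - 0.5))``, normalized over
    members.
    """
    presence_X = np.asarray(presence_X, dtype=float)
    background_X = np.asarray(background_X, dtype=float)
    var_index = {v: i for i, v in enumerate(variables)}
    members: list[SmallModel] = []
    log: list[dict] = []
    for subset in enumerate_subsets(variables, subset_size):
        cols = [var_index[v] for v in subset]
        Xp, Xb = presence_X[:, cols], background_X[:, cols]
        calib = np.vstack([Xp, Xb])
        best = None
        for classes in feature_classes:
            spec = FeatureSpec.from_data(calib, list(subset), classes=classes)
            for rm in reg_multipliers:
                aucs = []
                try:
                    for f in range(folds.k):
                        train = folds.fold != f
                        test = ~train
                        res = MaxentModel(Xp[train], Xb, spec, reg_multiplier=rm).fit()
                        aucs.append(
                            auc(res.raw_values(Xp[test]), res.raw_values(Xb))
                        )
                except ValueError as err:
                    warnings.warn(
                        f"skipping degenerate fit {subset} fc={classes} rm={rm}: {err}",
                        stacklevel=2,
                    )
                    continue
                mean_auc = float(np.mean(aucs))
                log.append(
                    {"subset": subset, "classes": classes, "reg": rm, "cv_auc": mean_auc}
                )
                if best is None or mean_auc > best[0]:
                    best = (mean_auc, classes, rm, spec)
        if best is None:
            warnings.warn(f"all fits failed for subset {subset}", stacklevel=2)
            continue
        cv_auc, classes, rm, spec = best
        final = MaxentModel(Xp, Xb, spec, reg_multiplier=rm).fit()
        members.append(
            SmallModel(
                variables=subset, classes=classes, reg_multiplier=rm,
                cv_auc=cv_auc, results=final,
            )
        )
    if not members:
        raise RuntimeError("every subset model failed to fit")
    raw_w = np.array([max(0.0, 2.0 * (m.cv_auc - 0.5)) for m in members])
    if raw_w.sum() > 0:
        weights = raw_w / raw_w.sum()
    else:
        warnings.warn(
            "no member exceeded AUC 0.5; falling back to the unweighted mean",
            stacklevel=2,
        )
        weights = np.full(len(members), 1.0 / len(members))
    return SmallModelEnsemble(members=members, weights=weights, tuning_log=log)


def ensemble_predict(ens: SmallModelEnsemble, stack: ClimateStack) -> GridRaster:
    """Accuracy-weighted mean of the members' logistic (HSI) maps."""
    w = ens.weights
    if w.sum() == 0:
        warnings.warn("all-zero weights; using the unweighted mean", stacklevel=2)
        w = np.full(len(ens.members), 1.0 / len(ens.members))
    out = None
    mask = None
    for member, wi in zip(ens.members, w):
        hsi = predict_logistic(member.results, stack)
        if out is None:
            out = wi * hsi.values
            mask = hsi.missing_mask.copy()
        else:
            out = out + wi * hsi.values
            mask |= hsi.missing_mask
    grid = stack.grid
    return GridRaster(out, cell_size=grid.cell_size, origin=grid.origin, missing_mask=mask)
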