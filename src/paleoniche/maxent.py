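"""Presence-background maximum-entropy niche model.

The estimator finds the Gibbs distribution over the landscape closest to
the background (prior) distribution Q subject to feature constraints: with
z(x) the feature vector at location x and I the coefficient vector, the
fitted occurrence density is

    P*(z(x_i)) = Q(x_i) exp(z(x_i) . I) / sum_i Q(x_i) exp(z(x_i) . I)

with Q uniform over the background sample.  Fitting maximizes the
L1-regularized mean presence log-likelihood of this distribution — a convex
problem, solved here by L-BFGS-B on the standard positive/negative
coefficient split.  The raw output is turned into a habitat suitability
index through the canonical entropy-calibrated logistic transform
``c r / (1 + c r)`` with ``c = exp(H)``, H the entropy of the fitted raw
distribution over the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .grids import ClimateStack, GridRaster

__all__ = ["FeatureSpec", "MaxentModel", "MaxentResults", "fit_maxent",
           "predict_raw", "predict_logistic"]

_CLASS_CODES = {"L": "linear", "Q": "quadratic", "P": "product", "H": "hinge",
                "T": "threshold"}


@dataclass
class FeatureSpec:
    """Feature construction recipe.

    ``classes`` is a string of class codes (subset of "LQPHT": linear,
    quadratic, product, hinge, threshold).  ``bounds`` holds per-variable
    (min, max) from the calibration data; every feature maps calibration
    values into [0, 1] and out-of-range projection values are clamped.
    Hinge/threshold knots live in the scaled [0, 1] space.
    """

    variables: list[str]
    classes: str = "LQ"
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    knots: dict[str, np.ndarray] = field(default_factory=dict)
    n_knots: int = 5

    def __post_init__(self) -> None:
        bad = set(self.classes) - set(_CLASS_CODES)
        if bad:
            raise ValueError(f"unknown feature class code(s): {sorted(bad)}")

    @classmethod
    def from_data(
        cls,
        X: np.ndarray,
        variables: list[str],
        classes: str = "LQ",
        n_knots: int = 5,
    ) -> "FeatureSpec":
        """Derive bounds (and evenly spaced interior knots) from calibration
        data ``X`` with columns in ``variables`` order."""
        X = np.asarray(X, dtype=float)
        bounds = {}
        for j, name in enumerate(variables):
            lo, hi = float(np.min(X[:, j])), float(np.max(X[:, j]))
            bounds[name] = (lo, hi)
        knots = {
            name: np.linspace(0, 1, n_knots + 2)[1:-1] for name in variables
        }
        return cls(variables=list(variables), classes=classes, bounds=bounds,
                   knots=knots, n_knots=n_knots)

    # -- scaling ------------------------------------------------------------
    def scale(self, X: np.ndarray) -> np.ndarray:
        """Clamp-and-scale raw variable columns into [0, 1]."""
        X = np.asarray(X, dtype=float)
        S = np.empty_like(X)
        for j, name in enumerate(self.variables):
            lo, hi = self.bounds[name]
            span = hi - lo if hi > lo else 1.0
            S[:, j] = np.clip((X[:, j] - lo) / span, 0.0, 1.0)
        return S


def build_features(X: np.ndarray, spec: FeatureSpec) -> tuple[np.ndarray, list[str]]:
    """Feature matrix for raw variable values ``X`` (columns = spec order).

    Returns ``(F, names)``; every column lies in [0, 1] on calibration data.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(spec.variables):
        raise ValueError("variable matrix does not match the feature spec")
    S = spec.scale(X)
    cols: list[np.ndarray] = []
    names: list[str] = []
    p = len(spec.variables)
    if "L" in spec.classes:
        for j, v in enumerate(spec.variables):
            cols.append(S[:, j])
            names.append(f"lin({v})")
    if "Q" in spec.classes:
        for j, v in enumerate(spec.variables):
            cols.append(S[:, j] ** 2)
            names.append(f"quad({v})")
    if "P" in spec.classes:
        for i in range(p):
            for j in range(i + 1, p):
                cols.append(S[:, i] * S[:, j])
                names.append(f"prod({spec.variables[i]},{spec.variables[j]})")
    if "H" in spec.classes:
        for j, v in enumerate(spec.variables):
            for k in spec.knots.get(v, np.linspace(0, 1, spec.n_knots + 2)[1:-1]):
                cols.append(np.maximum(0.0, (S[:, j] - k) / (1.0 - k)))
                names.append(f"hinge+({v},{k:.3f})")
                cols.append(np.maximum(0.0, (k - S[:, j]) / k))
                names.append(f"hinge-({v},{k:.3f})")
    if "T" in spec.classes:
        for j, v in enumerate(spec.variables):
            for k in spec.knots.get(v, np.linspace(0, 1, spec.n_knots + 2)[1:-1]):
                cols.append((S[:, j] > k).astype(float))
                names.append(f"thr({v},{k:.3f})")
    return np.column_stack(cols), names


@dataclass
class MaxentResults:
    """Fitted coefficients plus everything needed to project the model."""

    spec: FeatureSpec
    feature_names: list[str]
    coef: np.ndarray  # I, one entry per feature
    log_normalizer: float  # log sum_b exp(z_b . I) over the background
    entropy_H: float  # entropy (nats) of the raw distribution over background
    reg_multiplier: float
    converged: bool
    n_iter: int
    final_grad_norm: float
    n_presence: int
    n_background: int
    background_ref: str = ""

    # -- prediction ---------------------------------------------------------
    def raw_values(self, X: np.ndarray) -> np.ndarray:
        """Raw (normalized-density) scores for raw variable rows ``X``.

        Normalization uses the training background, so summing over the
        background sample returns exactly 1.
        """
        F, _ = build_features(X, self.spec)
        return np.exp(F @ self.coef - self.log_normalizer)

    def logistic_values(self, X: np.ndarray) -> np.ndarray:
        r = self.raw_values(X)
        c = np.exp(self.entropy_H)
        return c * r / (1.0 + c * r)


class MaxentModel:
    """Maximum-entropy presence-background model.

    Parameters
    ----------
    presence_X, background_X : ndarray
        Raw variable values at presence / background points, columns in
        ``spec.variables`` order.
    spec : FeatureSpec
        Feature construction recipe (bounds normally derived from the
        calibration points).
    reg_multiplier : float
        Scales the per-feature L1 penalty (default feature scales are the
        classic ``sqrt(var_presence(f) / n_presence)``).
    include_presences_in_background : bool
        Whether presences join the background sample used as Q for the
        normalization constant (the standard convention; default True).
    """

    def __init__(
        self,
        presence_X: np.ndarray,
        background_X: np.ndarray,
        spec: FeatureSpec,
        reg_multiplier: float = 1.0,
        include_presences_in_background: bool = True,
    ) -> None:
        if reg_multiplier <= 0:
            raise ValueError("reg_multiplier must be positive")
        presence_X = np.atleast_2d(np.asarray(presence_X, dtype=float))
        background_X = np.atleast_2d(np.asarray(background_X, dtype=float))
        if len(presence_X) < 1 or len(background_X) < 2:
            raise ValueError("need at least 1 presence and 2 background points")
        self.spec = spec
        self.reg_multiplier = float(reg_multiplier)
        self.F_p, self.feature_names = build_features(presence_X, spec)
        F_b, _ = build_features(background_X, spec)
        if include_presences_in_background:
            F_b = np.vstack([F_b, self.F_p])
        self.F_b = F_b
        if np.all(np.vstack([self.F_b, self.F_p]).std(axis=0) == 0):
            raise ValueError("degenerate fit: no variation in any feature")

    def fit(self, maxiter: int = 500, gtol: float = 1e-6) -> MaxentResults:
        """Minimize the penalized negative mean presence log-likelihood.

        The L1 term is handled exactly by the positive/negative coefficient
        split (I = a - b, a, b >= 0), keeping the problem smooth and convex
        for L-BFGS-B.
        """
        m = self.F_p.shape[1]
        mean_p = self.F_p.mean(axis=0)
        # classic Maxent default feature scales
        lam = np.sqrt(np.maximum(self.F_p.var(axis=0), 1e-12) / self.F_p.shape[0])
        beta = self.reg_multiplier * lam
        F_b = self.F_b

        def negloglik_grad(I: np.ndarray):
            eta = F_b @ I
            eta_max = eta.max()
            w = np.exp(eta - eta_max)
            Z = w.sum()
            nll = -(mean_p @ I) + np.log(Z) + eta_max
            grad = -mean_p + (F_b.T @ w) / Z
            return nll, grad

        def objective(ab: np.ndarray):
            a, b = ab[:m], ab[m:]
            nll, grad = negloglik_grad(a - b)
            pen = beta @ (a + b)
            return nll + pen, np.concatenate([grad + beta, -grad + beta])

        x0 = np.zeros(2 * m)
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None)] * (2 * m),
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        coef = res.x[:m] - res.x[m:]
        eta = F_b @ coef
        eta_max = eta.max()
        logZ = float(np.log(np.sum(np.exp(eta - eta_max))) + eta_max)
        p = np.exp(eta - logZ)
        H = float(-np.sum(p * np.log(np.clip(p, 1e-300, None))))
        # projected gradient norm: zero coefficients with |grad| <= beta are at optimum
        _, g = negloglik_grad(coef)
        pg = np.where(coef != 0, g + np.sign(coef) * beta, np.sign(g) * np.maximum(np.abs(g) - beta, 0.0))
        return MaxentResults(
            spec=self.spec,
            feature_names=self.feature_names,
            coef=coef,
            log_normalizer=logZ,
            entropy_H=H,
            reg_multiplier=self.reg_multiplier,
            converged=bool(res.success),
            n_iter=int(res.nit),
            final_grad_norm=float(np.linalg.norm(pg)),
            n_presence=self.F_p.shape[0],
            n_background=F_b.shape[0],
        )


def fit_maxent(
    presence_X: np.ndarray,
    background_X: np.ndarray,
    variables: list[str],
    classes: str = "LQ",
    reg_multiplier: float = 1.0,
    spec: FeatureSpec | None = None,
    **fit_kwargs,
) -> MaxentResults:
    """Convenience wrapper: build the feature spec from the calibration data
    (presences + background) and fit."""
    presence_X = np.atleast_2d(np.asarray(presence_X, dtype=float))
    background_X = np.atleast_2d(np.asarray(background_X, dtype=float))
    if spec is None:
        calib = np.vstack([presence_X, background_X])
        spec = FeatureSpec.from_data(calib, variables, classes=classes)
    model = MaxentModel(presence_X, background_X, spec, reg_multiplier=reg_multiplier)
    return model.fit(**fit_kwargs)


# ---------------------------------------------------------------------------
# raster prediction
# ---------------------------------------------------------------------------

def _stack_matrix(results: MaxentResults, stack: ClimateStack) -> tuple[np.ndarray, np.ndarray, GridRaster]:
    missing = [v for v in results.spec.variables if v not in stack]
    if missing:
        raise KeyError(f"stack lacks model variable(s): {missing}")
    grid = stack.grid
    mask = np.zeros(grid.shape, dtype=bool)
    for v in results.spec.variables:
        mask |= stack[v].missing_mask
    X = stack.to_matrix(results.spec.variables)
    return X, mask, grid


def predict_raw(results: MaxentResults, stack: ClimateStack) -> GridRaster:
    """Raw Gibbs density over a stack, normalized by the training background
    (so the raw scores of the background sample itself sum to 1)."""
    X, mask, grid = _stack_matrix(results, stack)
    raw = results.raw_values(X).reshape(grid.shape)
    raw[mask] = 0.0
    return GridRaster(raw, cell_size=grid.cell_size, origin=grid.origin, missing_mask=mask)


def predict_logistic(results: MaxentResults, stack: ClimateStack) -> GridRaster:
    """Habitat suitability index map: entropy-calibrated logistic output,
    per cell ``c r / (1 + c r)`` with ``c = exp(H)``; values in [0, 1]."""
    rawg = predict_raw(results, stack)
    c = np.exp(results.entropy_H)
    hsi = c * rawg.values / (1.0 + c * rawg.values)
    hsi[rawg.missing_mask] = 0.0
    return GridRaster(
        hsi, cell_size=rawg.cell_size, origin=rawg.origin, missing_mask=rawg.missing_mask
    )
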