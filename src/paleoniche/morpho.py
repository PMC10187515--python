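"""Morphometric classification suite.

Three procedures assign an unknown canid jaw to a species from the 19
dentognathic measurements:

* PCA of the log-transformed measurements over the extant comparative
  sample, with unknown ("fossil") specimens projected passively;
* stepwise linear discriminant analysis (forward selection by the Wilks
  lambda criterion) between groups — e.g. the three jackal species pooled
  against the Ethiopian wolf — validated by leave-one-out reclassification;
* bootstrap cluster analysis (BCA): a reference UPGMA dendrogram of the
  taxa in PCA score space, per-node bootstrap support from resampled
  specimens, and a sharpness test per partition level based on the G
  similarity index (pair-agreement between partitions, 0 = totally
  different, 1 = identical) against its expectation under random
  partitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .synthio import MEASUREMENT_NAMES

__all__ = [
    "MorphoPCA",
    "DiscriminantModel",
    "BCAResult",
    "log_pca",
    "fit_lda_stepwise",
    "apply_discriminant",
    "bca",
    "REFERENCE_WOLF_JACKAL_FUNCTION",
]

#: Published reference discriminant function separating the Ethiopian wolf
#: from the three jackal species on six dentognathic variables (raw mm
#: measurements; positive scores fall on the wolf side).
REFERENCE_WOLF_JACKAL_FUNCTION = {
    "coefficients": {
        "Lp4": -0.577,
        "Bp4": 1.545,
        "Lm1trig": 0.277,
        "Bm1tal": -0.839,
        "Lcm2": 0.256,
        "JBp3p4": -0.623,
    },
    "constant": -14.966,
}


# ---------------------------------------------------------------------------
# log-PCA
# ---------------------------------------------------------------------------

@dataclass
class MorphoPCA:
    loadings: np.ndarray  # (n_vars, n_components)
    eigenvalues: np.ndarray
    mean_log: np.ndarray
    scores: pd.DataFrame  # extant specimens: species + PC columns
    fossil_scores: pd.DataFrame  # projected unknowns (may be empty)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def log_pca(table: pd.DataFrame, fossil_label: str = "fossil") -> MorphoPCA:
    """Covariance-matrix PCA of log10 measurements.

    The rotation is fitted on the extant specimens only; rows labeled
    ``fossil_label`` are projected passively with the same centering and
    loadings.  Loading columns are oriented so their largest-magnitude
    entry is positive.
    """
    X = table[MEASUREMENT_NAMES].to_numpy(float)
    if (X <= 0).any():
        raise ValueError("all measurements must be positive for the log transform")
    L = np.log10(X)
    extant = (table["species"] != fossil_label).to_numpy()
    mu = L[extant].mean(axis=0)
    Z = L[extant] - mu
    cov = (Z.T @ Z) / max(1, Z.shape[0] - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    pc_names = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    S = (L - mu) @ eigvec
    scores = pd.DataFrame(S[extant], columns=pc_names)
    scores.insert(0, "species", table.loc[extant, "species"].to_numpy())
    fossil = pd.DataFrame(S[~extant], columns=pc_names)
    fossil.insert(0, "species", table.loc[~extant, "species"].to_numpy())
    return MorphoPCA(
        loadings=eigvec, eigenvalues=eigval, mean_log=mu, scores=scores,
        fossil_scores=fossil,
    )


# ---------------------------------------------------------------------------
# stepwise LDA
# ---------------------------------------------------------------------------

def _scatter(X: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(within-group SSCP, total SSCP)."""
    T = X - X.mean(axis=0)
    total = T.T @ T
    within = np.zeros_like(total)
    for g in np.unique(groups):
        sub = X[groups == g]
        D = sub - sub.mean(axis=0)
        within += D.T @ D
    return within, total


def wilks_lambda(X: np.ndarray, groups: np.ndarray) -> float:
    """|W| / |T|: the ratio of within-group to total scatter."""
    W, T = _scatter(X, groups)
    detT = np.linalg.det(T)
    if detT <= 0:
        return 1.0
    return float(np.linalg.det(W) / detT)


@dataclass
class DiscriminantModel:
    """Two-group linear discriminant with stepwise-selected variables.

    ``score = coefficients . x + constant``; scores are scaled to unit
    pooled within-group variance.  ``cut_point`` (R0) is the boundary
    between the groups, ``centroids`` the per-group mean scores (the target
    group's centroid is R1).  ``loo_table`` is the leave-one-out confusion
    table (rows = true group, columns = predicted).
    """

    variables: list[str]
    coefficients: np.ndarray
    constant: float
    group_labels: list[str]
    centroids: dict[str, float]
    cut_point: float
    lambda_wilks: float
    chi2: float
    chi2_pvalue: float
    loo_table: pd.DataFrame
    posteriors: pd.DataFrame
    step_log: list[dict] = field(default_factory=list)

    def score(self, measurements) -> float:
        x = np.array([_get_measurement(measurements, v) for v in self.variables])
        return float(self.coefficients @ x + self.constant)

    def classify(self, measurements) -> tuple[float, str, float]:
        return apply_discriminant(
            dict(zip(self.variables, self.coefficients)),
            self.constant,
            measurements,
            centroids=self.centroids,
            cut_point=self.cut_point,
        )

    def summary(self) -> str:
        terms = " ".join(
            f"{c:+.3f}*{v}" for v, c in zip(self.variables, self.coefficients)
        )
        loo_rate = 100.0 * np.trace(self.loo_table.to_numpy()) / self.loo_table.to_numpy().sum()
        return (
            f"discriminant function: {terms} {self.constant:+.3f}\n"
            f"Wilks lambda = {self.lambda_wilks:.3f}, chi2 = {self.chi2:.3f} "
            f"(p = {self.chi2_pvalue:.2g})\n"
            f"leave-one-out reclassification: {loo_rate:.1f} %"
        )


def _get_measurement(measurements, name: str) -> float:
    try:
        if isinstance(measurements, (pd.Series, dict)):
            return float(measurements[name])
        return float(measurements[name])
    except (KeyError, IndexError) as err:
        raise KeyError(f"missing required measurement: {name}") from err


def fit_lda_stepwise(
    table: pd.DataFrame,
    group_of: dict[str, str],
    f_to_enter: float = 3.84,
    max_variables: int | None = None,
    use_log: bool = False,
) -> DiscriminantModel:
    """Forward stepwise two-group LDA with the Wilks lambda entry criterion.

    ``group_of`` maps species labels to one of exactly two group labels;
    unmapped rows are ignored.  At each step the candidate variable with
    the smallest Wilks lambda enters if its partial F exceeds
    ``f_to_enter``.  Raw millimetre measurements are used by default
    (``use_log`` switches to log10).
    """
    sub = table[table["species"].isin(group_of)].copy()
    groups = sub["species"].map(group_of).to_numpy()
    labels = sorted(set(group_of.values()))
    if len(labels) != 2:
        raise ValueError("stepwise LDA here is two-group: map species to two labels")
    X_all = sub[MEASUREMENT_NAMES].to_numpy(float)
    if use_log:
        X_all = np.log10(X_all)
    n, g = len(sub), 2
    for lbl in labels:
        if (groups == lbl).sum() < 2:
            raise ValueError(f"group {lbl} needs at least two specimens")

    selected: list[int] = []
    lam_current = 1.0
    step_log = []
    remaining = list(range(len(MEASUREMENT_NAMES)))
    limit = max_variables or len(MEASUREMENT_NAMES)
    while remaining and len(selected) < limit:
        best = None
        for j in remaining:
            cols = selected + [j]
            lam = wilks_lambda(X_all[:, cols], groups)
            if best is None or lam < best[0]:
                best = (lam, j)
        lam_new, j_best = best
        q = len(selected)
        if lam_new <= 0 or lam_new >= lam_current:
            break
        F = (n - g - q) / (g - 1) * (lam_current / lam_new - 1.0)
        if F < f_to_enter:
            break
        selected.append(j_best)
        remaining.remove(j_best)
        lam_current = lam_new
        step_log.append(
            {"variable": MEASUREMENT_NAMES[j_best], "wilks_lambda": lam_new, "F_to_enter": F}
        )
    if not selected:
        raise ValueError("no variable met the entry criterion (groups indistinguishable)")

    variables = [MEASUREMENT_NAMES[j] for j in selected]
    X = X_all[:, selected]
    p = X.shape[1]
    lam = lam_current
    chi2 = -(n - 1 - (p + g) / 2.0) * np.log(lam) if lam > 0 else np.inf
    chi2_p = float(stats.chi2.sf(chi2, df=p * (g - 1)))

    w, const, cents = _two_group_function(X, groups, labels)
    cut = 0.5 * (cents[labels[0]] + cents[labels[1]])

    # leave-one-out reclassification with the selected variables fixed
    pred = []
    for i in range(n):
        keep = np.arange(n) != i
        wi, ci, cents_i = _two_group_function(X[keep], groups[keep], labels)
        cut_i = 0.5 * (cents_i[labels[0]] + cents_i[labels[1]])
        s = X[i] @ wi + ci
        hi = labels[0] if (cents_i[labels[0]] > cents_i[labels[1]]) == (s > cut_i) else labels[1]
        pred.append(hi)
    loo = pd.crosstab(
        pd.Series(groups, name="true"), pd.Series(pred, name="predicted")
    ).reindex(index=labels, columns=labels, fill_value=0)

    scores = X @ w + const
    d = cents[labels[1]] - cents[labels[0]]
    post1 = 1.0 / (1.0 + np.exp(d * (scores - cut)))  # posterior of labels[0]
    posteriors = pd.DataFrame(
        {
            "species": sub["species"].to_numpy(),
            "group": groups,
            "score": scores,
            f"p_{labels[0]}": post1,
            f"p_{labels[1]}": 1.0 - post1,
        }
    )
    return DiscriminantModel(
        variables=variables,
        coefficients=w,
        constant=const,
        group_labels=labels,
        centroids=cents,
        cut_point=cut,
        lambda_wilks=lam,
        chi2=float(chi2),
        chi2_pvalue=chi2_p,
        loo_table=loo,
        posteriors=posteriors,
        step_log=step_log,
    )


def _two_group_function(
    X: np.ndarray, groups: np.ndarray, labels: list[str]
) -> tuple[np.ndarray, float, dict[str, float]]:
    """Fisher coefficients scaled to unit pooled within-group score
    variance, grand-mean-centered constant, and per-group mean scores."""
    W, _ = _scatter(X, groups)
    n = len(X)
    Sw = W / (n - 2)
    m0 = X[groups == labels[0]].mean(axis=0)
    m1 = X[groups == labels[1]].mean(axis=0)
    w = np.linalg.solve(Sw, m1 - m0)
    scale = np.sqrt(w @ Sw @ w)
    if scale > 0:
        w = w / scale
    const = -float(w @ X.mean(axis=0))
    cents = {
        labels[0]: float(m0 @ w + const),
        labels[1]: float(m1 @ w + const),
    }
    return w, const, cents


def apply_discriminant(
    coefficients: dict[str, float],
    constant: float,
    measurements,
    centroids: dict[str, float] | None = None,
    cut_point: float = 0.0,
) -> tuple[float, str | None, float | None]:
    """Evaluate a linear discriminant function on one specimen.

    Returns ``(score, class_label, posterior)``.  The class is the side of
    ``cut_point`` (R0) the score falls on, named by the nearer centroid when
    centroids are given; the posterior comes from the equal-variance
    Gaussian model on the score axis.  A missing measurement raises a
    ``KeyError`` naming the variable.
    """
    score = float(
        sum(c * _get_measurement(measurements, v) for v, c in coefficients.items())
        + constant
    )
    if centroids is None:
        return score, None, None
    (la, ca), (lb, cb) = centroids.items()
    if abs(score - ca) <= abs(score - cb):
        label, d_own, d_other = la, ca, cb
    else:
        label, d_own, d_other = lb, cb, ca
    delta = d_other - d_own
    posterior = float(1.0 / (1.0 + np.exp(delta * (score - 0.5 * (d_own + d_other)))))
    return score, label, posterior


# ---------------------------------------------------------------------------
# bootstrap cluster analysis
# ---------------------------------------------------------------------------

def _partition_at(Z: np.ndarray, k: int) -> np.ndarray:
    return fcluster(Z, t=k, criterion="maxclust")


def _pair_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """G similarity between two partitions: the fraction of taxon pairs on
    which they agree (both together or both apart); 0..1, 1 = identical."""
    n = len(a)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    iu = np.triu_indices(n, k=1)
    return float(np.mean(same_a[iu] == same_b[iu]))


def _node_sets(Z: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Taxon set of every internal node of a linkage tree."""
    n = len(labels)
    sets: dict[int, frozenset] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for i, (a, b, _, _) in enumerate(Z):
        s = sets[int(a)] | sets[int(b)]
        sets[n + i] = s
        out.append(s)
    return out


@dataclass
class BCAResult:
    taxa: list[str]
    reference_linkage: np.ndarray
    node_support: dict[frozenset, float]  # percentage of replicates
    g_star: dict[int, np.ndarray]  # per partition level, replicate G* values
    g_null: dict[int, np.ndarray]  # per level, null G values
    sharp: dict[int, bool]
    alpha: float

    def support_of(self, taxa: set[str]) -> float:
        return self.node_support.get(frozenset(taxa), 0.0)

    def to_newick(self) -> str:
        """Newick string with node support percentages as internal labels."""
        n = len(self.taxa)
        sets = _node_sets(self.reference_linkage, self.taxa)

        def render(idx: int) -> str:
            if idx < n:
                return self.taxa[idx].replace(" ", "_")
            a, b, h, _ = self.reference_linkage[idx - n]
            sup = self.node_support.get(sets[idx - n], 0.0)
            return f"({render(int(a))},{render(int(b))}){sup:.0f}:{h:.4f}"

        return render(n + len(self.reference_linkage) - 1) + ";"


def bca(
    scores: pd.DataFrame,
    n_components: int = 2,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BCAResult:
    """Bootstrap cluster analysis of taxa in PCA score space.

    The reference dendrogram is a UPGMA (average-linkage) tree on the
    Euclidean distances between taxon centroids of the first
    ``n_components`` score columns.  Each of ``n_boot`` replicates
    resamples specimens within each taxon with replacement, reclusters the
    centroids, and contributes (1) to the support of every reference node
    whose taxon set it reproduces and (2) a G* pair-agreement value per
    partition level.  The null G (G deg) per level comes from comparing the
    reference partition with a randomly relabeled partition of the same
    cluster sizes; a level is sharp when the estimated P(G deg <= G*)
    exceeds ``alpha``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pc_cols = [c for c in scores.columns if c.startswith("PC")][:n_components]
    taxa = list(pd.unique(scores["species"]))
    if len(taxa) < 3:
        raise ValueError("BCA needs at least three taxa")
    groups = {t: scores.loc[scores["species"] == t, pc_cols].to_numpy(float) for t in taxa}

    def centroids(g: dict[str, np.ndarray]) -> np.ndarray:
        return np.vstack([g[t].mean(axis=0) for t in taxa])

    ref_Z = linkage(pdist(centroids(groups)), method="average")
    ref_sets = _node_sets(ref_Z, taxa)
    ref_parts = {k: _partition_at(ref_Z, k) for k in range(2, len(taxa))}

    rng = np.random.default_rng(seed)
    support = {s: 0 for s in ref_sets}
    g_star: dict[int, list[float]] = {k: [] for k in ref_parts}
    g_null: dict[int, list[float]] = {k: [] for k in ref_parts}
    for _ in range(n_boot):
        boot = {
            t: g[rng.integers(0, len(g), size=len(g))] for t, g in groups.items()
        }
        Z = linkage(pdist(centroids(boot)), method="average")
        for s in _node_sets(Z, taxa):
            if s in support:
                support[s] += 1
        for k, ref_p in ref_parts.items():
            rep_p = _partition_at(Z, k)
            g_star[k].append(_pair_agreement(ref_p, rep_p))
            g_null[k].append(_pair_agreement(ref_p, rng.permutation(rep_p)))
    node_support = {s: 100.0 * c / n_boot for s, c in support.items()}
    g_star_a = {k: np.array(v) for k, v in g_star.items()}
    g_null_a = {k: np.array(v) for k, v in g_null.items()}
    sharp = {
        k: bool(np.mean(g_null_a[k] <= g_star_a[k]) > alpha) for k in ref_parts
    }
    return BCAResult(
        taxa=taxa, reference_linkage=ref_Z, node_support=node_support,
        g_star=g_star_a, g_null=g_null_a, sharp=sharp, alpha=alpha,
    )
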