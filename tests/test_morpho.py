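"""Morphometric suite: log-PCA eigenstructure, stepwise discriminant
selection and leave-one-out validation, the reference discriminant
function, and bootstrap cluster analysis."""

import numpy as np
import pandas as pd
import pytest

from paleoniche.morpho import (
    REFERENCE_WOLF_JACKAL_FUNCTION,
    apply_discriminant,
    bca,
    fit_lda_stepwise,
    log_pca,
    wilks_lambda,
)
from paleoniche.synthio import MEASUREMENT_NAMES, generate_morpho_table, MorphoConfig

JACKAL_WOLF_GROUPS = {
    "Canis aureus": "jackal",
    "Lupulella adusta": "jackal",
    "Lupulella mesomelas": "jackal",
    "Canis simensis": "wolf",
}


def _table_from_matrix(X, species):
    df = pd.DataFrame(X, columns=MEASUREMENT_NAMES)
    df.insert(0, "species", species)
    return df


class TestLogPCA:
    def test_scores_match_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(0)
        X = np.exp(rng.normal(2, 0.1, size=(6, 19)))
        tab = _table_from_matrix(X, ["sp1"] * 3 + ["sp2"] * 3)
        p = log_pca(tab)
        L = np.log10(X)
        C = np.cov(L.T)
        ev = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(p.eigenvalues, np.clip(ev, 0, None), atol=1e-12)
        # score variances equal eigenvalues
        S = p.scores[[f"PC{i+1}" for i in range(5)]].to_numpy()
        np.testing.assert_allclose(S.var(axis=0, ddof=1), p.eigenvalues[:5], atol=1e-12)

    def test_identical_specimens_degenerate_but_graceful(self):
        X = np.tile(np.linspace(5, 80, 19), (4, 1))
        tab = _table_from_matrix(X, ["a", "a", "b", "b"])
        p = log_pca(tab)
        np.testing.assert_allclose(p.eigenvalues, 0.0, atol=1e-20)

    def test_fossil_projection_invariant_to_row_order(self, morpho_table):
        p1 = log_pca(morpho_table)
        shuffled = morpho_table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        p2 = log_pca(shuffled)
        np.testing.assert_allclose(
            p1.fossil_scores["PC1"].to_numpy(), p2.fossil_scores["PC1"].to_numpy(), atol=1e-10
        )

    def test_hypercarnivores_separate_on_pc1(self, morpho_table):
        p = log_pca(morpho_table)
        means = p.scores.groupby("species")["PC1"].mean()
        hyper = ["Canis lupus", "Lycaon pictus", "Cuon alpinus"]
        meso = [s for s in means.index if s not in hyper]
        assert means[hyper].min() > means[meso].max()

    def test_nonpositive_measurement_rejected(self):
        X = np.ones((3, 19))
        X[0, 0] = -1
        with pytest.raises(ValueError):
            log_pca(_table_from_matrix(X, ["a", "a", "b"]))


class TestStepwiseLDA:
    def test_well_separated_groups_reclassify_perfectly(self):
        """Mahalanobis-separated synthetic groups: leave-one-out
        reclassification is 100 %."""
        rng = np.random.default_rng(1)
        base = np.linspace(10, 60, 19)
        Xa = base + rng.normal(0, 1, size=(25, 19))
        Xb = base + 8.0 * np.r_[np.ones(5), np.zeros(14)] + rng.normal(0, 1, size=(25, 19))
        tab = _table_from_matrix(np.vstack([Xa, Xb]), ["A"] * 25 + ["B"] * 25)
        m = fit_lda_stepwise(tab, {"A": "g1", "B": "g2"})
        loo = m.loo_table.to_numpy()
        assert np.trace(loo) == loo.sum() == 50
        assert m.lambda_wilks < 0.2

    def test_identical_means_leave_groups_indistinguishable(self):
        """With no true mean difference either no variable meets the entry
        criterion, or whatever enters by chance leaves Wilks lambda near 1
        and near-chance leave-one-out accuracy."""
        rng = np.random.default_rng(2)
        base = np.linspace(10, 60, 19)
        X = base + rng.normal(0, 1, size=(40, 19))
        tab = _table_from_matrix(X, ["A"] * 20 + ["B"] * 20)
        try:
            m = fit_lda_stepwise(tab, {"A": "g1", "B": "g2"})
        except ValueError as err:
            assert "entry criterion" in str(err)
        else:
            assert m.lambda_wilks > 0.6
            loo = m.loo_table.to_numpy()
            assert np.trace(loo) / loo.sum() < 0.85

    def test_wilks_lambda_matches_determinant_ratio(self):
        """Two-variable toy instance: lambda = |W| / |T| computed from the
        scatter matrices directly."""
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(2, 1, (10, 2))])
        g = np.array(["a"] * 10 + ["b"] * 10)
        T = X - X.mean(0)
        W = np.vstack([X[:10] - X[:10].mean(0), X[10:] - X[10:].mean(0)])
        lam_direct = np.linalg.det(W.T @ W) / np.linalg.det(T.T @ T)
        assert wilks_lambda(X, g) == pytest.approx(lam_direct)

    def test_default_sample_separates_wolf_from_jackals(self, morpho_table):
        m = fit_lda_stepwise(morpho_table, JACKAL_WOLF_GROUPS)
        loo = m.loo_table.to_numpy()
        assert loo.sum() == 81  # 61 jackals + 20 wolves
        assert np.trace(loo) / loo.sum() > 0.95
        fossil = morpho_table[morpho_table.species == "fossil"].iloc[0]
        score, label, post = m.classify(fossil)
        assert label == "wolf" and post > 0.5

    def test_scaling_invariance_of_loo_rate(self, morpho_table):
        """Rescaling variables by positive constants leaves LDA's LOO
        reclassification unchanged (affine equivariance)."""
        m1 = fit_lda_stepwise(morpho_table, JACKAL_WOLF_GROUPS)
        scaled = morpho_table.copy()
        rng = np.random.default_rng(4)
        factors = rng.uniform(0.5, 2.0, size=19)
        scaled[MEASUREMENT_NAMES] = scaled[MEASUREMENT_NAMES] * factors
        m2 = fit_lda_stepwise(scaled, JACKAL_WOLF_GROUPS)
        r1 = np.trace(m1.loo_table.to_numpy()) / m1.loo_table.to_numpy().sum()
        r2 = np.trace(m2.loo_table.to_numpy()) / m2.loo_table.to_numpy().sum()
        assert r1 == pytest.approx(r2)


class TestApplyDiscriminant:
    def test_reference_function_constant_at_zero_vector(self):
        coeffs = REFERENCE_WOLF_JACKAL_FUNCTION["coefficients"]
        score, _, _ = apply_discriminant(
            coeffs, REFERENCE_WOLF_JACKAL_FUNCTION["constant"],
            {k: 0.0 for k in coeffs},
        )
        assert score == pytest.approx(-14.966)

    def test_unit_increase_in_bp4(self):
        coeffs = REFERENCE_WOLF_JACKAL_FUNCTION["coefficients"]
        const = REFERENCE_WOLF_JACKAL_FUNCTION["constant"]
        x0 = {k: 1.0 for k in coeffs}
        x1 = dict(x0, Bp4=2.0)
        s0, _, _ = apply_discriminant(coeffs, const, x0)
        s1, _, _ = apply_discriminant(coeffs, const, x1)
        assert s1 - s0 == pytest.approx(1.545)

    def test_missing_variable_named(self):
        coeffs = REFERENCE_WOLF_JACKAL_FUNCTION["coefficients"]
        nearly_complete = {k: 1.0 for k in coeffs if k != "JBp3p4"}
        with pytest.raises(KeyError, match="JBp3p4"):
            apply_discriminant(coeffs, -14.966, nearly_complete)

    def test_score_at_centroid_equals_stored_centroid(self, morpho_table):
        m = fit_lda_stepwise(morpho_table, JACKAL_WOLF_GROUPS)
        wolves = morpho_table[morpho_table.species == "Canis simensis"]
        mean_meas = wolves[m.variables].mean()
        assert m.score(mean_meas) == pytest.approx(m.centroids["wolf"], abs=1e-8)


class TestBCA:
    def _scores(self, centers, n=10, sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for name, c in centers.items():
            pts = rng.normal(c, sd, size=(n, len(c)))
            for p in pts:
                rows.append({"species": name, "PC1": p[0], "PC2": p[1]})
        return pd.DataFrame(rows)

    def test_full_data_replicate_is_identical(self):
        scores = self._scores({"A": (0, 0), "B": (1, 0), "C": (10, 0)}, sd=0.0)
        r = bca(scores, n_boot=5, seed=0)
        for k, g in r.g_star.items():
            np.testing.assert_allclose(g, 1.0)

    def test_unambiguous_three_taxon_join(self):
        """d(A,B) = 1, d(A,C) = d(B,C) ~ 10: UPGMA joins A and B first and
        bootstrap support for that node is ~100 %."""
        scores = self._scores({"A": (0.0, 0.0), "B": (1.0, 0.0), "C": (10.0, 0.0)},
                              sd=0.05, seed=1)
        r = bca(scores, n_boot=200, seed=2)
        assert r.support_of({"A", "B"}) > 99.0
        # hand UPGMA: first merge is (A, B)
        first = r.reference_linkage[0, :2].astype(int)
        assert set(first) == {0, 1}

    def test_no_structure_gives_weak_support(self):
        """Interleaved taxa with no real grouping: average support for the
        two-taxon reference nodes stays well below 95 %."""
        rng = np.random.default_rng(3)
        rows = []
        for name in "ABCD":
            for _ in range(12):
                p = rng.normal(0, 1, 2)
                rows.append({"species": name, "PC1": p[0], "PC2": p[1]})
        r = bca(pd.DataFrame(rows), n_boot=150, seed=4)
        pair_supports = [v for s, v in r.node_support.items() if len(s) == 2]
        assert np.mean(pair_supports) < 80

    def test_reproducible_and_converging_support(self):
        scores = self._scores({"A": (0, 0), "B": (1.5, 0), "C": (8, 0), "D": (9, 1)},
                              sd=0.3, seed=5)
        r1 = bca(scores, n_boot=300, seed=6)
        r2 = bca(scores, n_boot=300, seed=6)
        assert r1.node_support == r2.node_support
        r3 = bca(scores, n_boot=600, seed=7)
        for s, v in r1.node_support.items():
            assert abs(v - r3.node_support[s]) <= 5.0

    def test_upgma_heights_monotone(self, morpho_table):
        r = bca(log_pca(morpho_table).scores, n_boot=20, seed=8)
        heights = r.reference_linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_newick_contains_all_taxa_and_supports(self, morpho_table):
        r = bca(log_pca(morpho_table).scores, n_boot=20, seed=9)
        nwk = r.to_newick()
        for t in r.taxa:
            assert t.replace(" ", "_") in nwk
        assert nwk.endswith(";")

    def test_too_few_taxa_rejected(self):
        scores = self._scores({"A": (0, 0), "B": (1, 0)})
        with pytest.raises(ValueError):
            bca(scores, n_boot=10)
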