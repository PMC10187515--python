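"""Landscape fragmentation: class binning, patch metrics vs hand oracles
and a flood-fill labeller, PerMANOVA vs classical ANOVA and its null
calibration, and the scenario regressions."""

import numpy as np
import pandas as pd
import pytest

from paleoniche.grids import GridRaster
from paleoniche.landscape import (
    classify_hsi,
    class_metric_glm,
    landscape_table,
    patch_area_trend,
    patch_metrics,
    permanova_two_way,
    pairwise_permanova,
    prepare_landscape_response,
)


def _cmap(values):
    return GridRaster(np.asarray(values, dtype=float))


class TestClassify:
    @pytest.mark.parametrize(
        "hsi,expected",
        [(0.0, 1), (0.24, 1), (0.25, 2), (0.49, 2), (0.5, 3), (0.74, 3), (0.75, 4), (1.0, 4)],
    )
    def test_bin_boundaries(self, hsi, expected):
        cm = classify_hsi(GridRaster(np.array([[hsi]])))
        assert cm.values[0, 0] == expected

    def test_counts_partition_valid_cells(self):
        rng = np.random.default_rng(0)
        hsi = GridRaster(rng.uniform(size=(10, 10)))
        cm = classify_hsi(hsi)
        counts = [(cm.values == c).sum() for c in (1, 2, 3, 4)]
        assert sum(counts) == 100


class TestPatchMetrics:
    def test_full_landscape_single_patch(self):
        m = patch_metrics(_cmap(np.ones((5, 5))), 1)
        assert m["np"] == 1 and m["division"] == pytest.approx(0.0)
        assert m["cohesion"] == pytest.approx(100.0)

    def test_checkerboard_has_zero_aggregation(self):
        v = np.indices((6, 6)).sum(axis=0) % 2
        m = patch_metrics(_cmap(v), 1)
        assert m["ai"] == 0.0
        assert m["np"] == 18

    def test_two_by_two_block_oracle(self):
        v = np.zeros((4, 4))
        v[1:3, 1:3] = 1
        m = patch_metrics(_cmap(v), 1)
        assert m["np"] == 1
        assert m["area_mn"] == pytest.approx(4.0)
        assert m["ai"] == pytest.approx(100.0)  # 4 like-adjacencies = maximum

    def test_absent_class(self):
        m = patch_metrics(_cmap(np.ones((3, 3))), 2)
        assert m["np"] == 0 and np.isnan(m["area_mn"])

    def test_patch_count_matches_flood_fill_oracle(self):
        """Brute-force 4-neighbour flood fill on random small grids."""

        def flood_count(mask):
            seen = np.zeros_like(mask, bool)
            count = 0
            for i in range(mask.shape[0]):
                for j in range(mask.shape[1]):
                    if mask[i, j] and not seen[i, j]:
                        count += 1
                        stack = [(i, j)]
                        while stack:
                            a, b = stack.pop()
                            if not (0 <= a < mask.shape[0] and 0 <= b < mask.shape[1]):
                                continue
                            if not mask[a, b] or seen[a, b]:
                                continue
                            seen[a, b] = True
                            stack += [(a + 1, b), (a - 1, b), (a, b + 1), (a, b - 1)]
            return count

        rng = np.random.default_rng(1)
        for _ in range(25):
            v = rng.integers(0, 3, size=(8, 8))
            for c in (0, 1, 2):
                if (v == c).any():
                    m = patch_metrics(_cmap(v), c)
                    assert m["np"] == flood_count(v == c)

    def test_metric_ranges_on_random_maps(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            v = rng.integers(1, 5, size=(7, 7))
            for c in range(1, 5):
                if not (v == c).any():
                    continue
                m = patch_metrics(_cmap(v), c)
                assert m["np"] >= 1
                assert 0 <= m["ai"] <= 100
                assert -1 <= m["clumpy"] <= 1
                assert 0 <= m["cohesion"] <= 100
                assert 0 <= m["division"] <= 1

    def test_empty_landscape_rejected(self):
        g = GridRaster(np.zeros((2, 2)), missing_mask=np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="empty landscape"):
            patch_metrics(g, 1)


class TestPerMANOVA:
    def test_constant_response_zero_f(self):
        y = np.ones(12)
        fa = np.repeat(["a", "b", "c"], 4)
        fb = np.tile(["x", "y"], 6)
        res = permanova_two_way(y, fa, fb, n_perm=19, seed=0)
        assert (res["pseudo_F"] == 0).all()

    def test_univariate_single_factor_equals_anova_f(self):
        """With a univariate response and free permutations the pseudo-F of
        each sequential term equals the classical sequential ANOVA F."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(3)
        y = rng.normal(size=18)
        fa = np.repeat(["a", "b", "c"], 6)
        fb = np.tile(["x", "y", "z"], 6)
        res = permanova_two_way(y, fa, fb, n_perm=9, seed=0)
        an = sm.stats.anova_lm(
            smf.ols("y ~ fa + fb", pd.DataFrame({"y": y, "fa": fa, "fb": fb})).fit()
        )
        assert res.loc[0, "pseudo_F"] == pytest.approx(an.loc["fa", "F"])
        assert res.loc[1, "pseudo_F"] == pytest.approx(an.loc["fb", "F"])

    def test_null_p_values_approximately_uniform(self):
        """Under a simulated null the permutation p-value is approximately
        uniform (KS test over replicates at reduced permutation count)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(4)
        fa = np.repeat(["a", "b"], 6)
        fb = np.tile(["x", "y"], 6)
        ps = []
        for i in range(300):
            y = rng.normal(size=(12, 2))
            res = permanova_two_way(y, fa, fb, n_perm=49, seed=i)
            ps.append(res.loc[0, "p"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_signal_detected_with_stratified_permutations(self):
        rng = np.random.default_rng(5)
        fa = np.repeat(["a", "b"], 8)
        fb = np.tile(["x", "y"], 8)
        strata = np.tile(["s1", "s1", "s2", "s2"], 4)
        y = np.where(fa == "a", 0.0, 3.0) + rng.normal(scale=0.5, size=16)
        res = permanova_two_way(y, fa, fb, strata=strata, n_perm=199, seed=1)
        assert res.loc[0, "p"] < 0.05

    def test_pairwise_follow_up(self):
        rng = np.random.default_rng(6)
        f = np.repeat(["a", "b", "c"], 6)
        y = np.where(f == "c", 5.0, 0.0) + rng.normal(scale=0.5, size=18)
        pw = pairwise_permanova(y, f, n_perm=199, seed=2)
        assert len(pw) == 3
        assert pw.set_index("pair").loc["a vs c", "p"] < 0.05
        assert pw.set_index("pair").loc["a vs b", "p"] > 0.05

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            permanova_two_way(np.ones(4), ["a"] * 4, ["x", "y", "x", "y"], n_perm=9)


def _metric_table(area_factor=0.5):
    """Synthetic per-scenario metric table: mean patch area halves each
    period step; other metrics vary mildly."""
    rows = []
    rng = np.random.default_rng(7)
    for emu in ("E1", "E2"):
        for ssp in ("126", "585"):
            for k, period in enumerate((0, 1, 2, 3)):
                for cls in (2, 3, 4):
                    rows.append(
                        {
                            "emulator": emu, "ssp": ssp, "period": period, "class": cls,
                            "np": 5 + cls + rng.normal(0, 0.1),
                            "area_mn": 64.0 * (area_factor**k) * (1 + 0.1 * cls),
                            "ai": 50 + 5 * cls + rng.normal(0, 1),
                            "clumpy": 0.1 * cls + rng.normal(0, 0.01),
                            "cohesion": 60 + 8 * cls + rng.normal(0, 1),
                            "division": 0.99,
                        }
                    )
    return pd.DataFrame(rows)


class TestRegressions:
    def test_area_halving_gives_log_half_slope(self):
        tab = _metric_table(area_factor=0.5)
        fits = patch_area_trend(tab)
        for emu, fit in fits.items():
            assert fit.params["period"] == pytest.approx(np.log10(0.5), abs=1e-6)

    def test_constant_area_zero_slope(self):
        tab = _metric_table(area_factor=1.0)
        fits = patch_area_trend(tab)
        for fit in fits.values():
            assert fit.params["period"] == pytest.approx(0.0, abs=1e-9)

    def test_coefficients_match_normal_equations(self):
        tab = _metric_table()
        fit = patch_area_trend(tab)["E1"]
        sub = tab[tab.emulator == "E1"]
        X = np.column_stack(
            [
                np.ones(len(sub)),
                (sub["class"] == 3).astype(float),
                (sub["class"] == 4).astype(float),
                sub["period"],
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ np.log10(sub["area_mn"]))
        assert fit.params["period"] == pytest.approx(beta[3])

    def test_ordered_cohesion_gradient_detected(self):
        tab = _metric_table()
        res = class_metric_glm(tab, metrics=["cohesion"])["E1"]
        assert res.params["cohesion"] > 0

    def test_exclusions_in_response_preparation(self):
        tab = _metric_table()
        kept, Y = prepare_landscape_response(tab)
        assert (kept["class"] != 1).all()
        assert Y.shape[0] == len(kept)
        # division (zero variance) never enters
        assert Y.shape[1] <= 5
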