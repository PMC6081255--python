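"""Statistical machinery tests: univariate tests, ROC, stepwise logistic,
feature selection, DeLong."""

import numpy as np
import pandas as pd
import pytest

from plaque_radiomics.stats import (
    auc_mann_whitney,
    chi_squared_2x2,
    delong_test,
    likelihood_ratios,
    optimise_operating_point,
    roc_points,
    select_radiomic_features,
    stepwise_logistic,
    two_sample_ttest,
)

from oracles import brute_auc


class TestTTest:
    def test_identical_groups(self):
        r = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_matches_textbook_pooled_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        r = two_sample_ttest(a, b)
        sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / (
            len(a) + len(b) - 2
        )
        t_expected = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        assert r.statistic == pytest.approx(t_expected)
        from scipy.stats import t as tdist

        p_expected = 2 * tdist.sf(abs(t_expected), df=4)
        assert r.p_value == pytest.approx(p_expected)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=12)
        r1 = two_sample_ttest(a, b)
        r2 = two_sample_ttest(a + 5.5, b + 5.5)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_zero_variance_sentinels(self):
        same = two_sample_ttest([2.0, 2.0], [2.0, 2.0])
        assert same.p_value == 1.0
        diff = two_sample_ttest([2.0, 2.0], [3.0, 3.0])
        assert diff.p_value == 0.0


class TestChiSquared:
    def test_independent_table(self):
        # Outer product of the marginals: no association at all.
        r = chi_squared_2x2([[20, 30], [40, 60]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_expected_counts(self):
        table = np.array([[46.0, 15.0], [18.0, 17.0]])
        n = table.sum()
        expected_stat = 0.0
        for i in range(2):
            for j in range(2):
                e = table[i].sum() * table[:, j].sum() / n
                expected_stat += (table[i, j] - e) ** 2 / e
        r = chi_squared_2x2(table)
        assert r.statistic == pytest.approx(expected_stat)
        assert r.statistic == pytest.approx(5.75, abs=0.01)

    def test_transpose_invariance(self):
        t = [[12, 5], [7, 20]]
        assert chi_squared_2x2(t).statistic == pytest.approx(
            chi_squared_2x2(np.transpose(t)).statistic
        )

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_2x2([[0, 0], [5, 7]])


class TestAuc:
    def test_perfect_separation(self):
        assert auc_mann_whitney([1, 2, 8, 9], [0, 0, 1, 1]) == 1.0

    def test_all_tied(self):
        assert auc_mann_whitney([3, 3, 3, 3], [0, 0, 1, 1]) == 0.5

    def test_small_example_brute_forced(self):
        scores = [3.0, 2.0, 1.0, 2.5]
        labels = [1, 1, 0, 0]
        assert auc_mann_whitney(scores, labels) == pytest.approx(0.75)

    def test_matches_pairwise_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(4, 15))
            scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                brute_auc(scores, labels)
            )

    def test_equals_trapezoid_for_tie_free_scores(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(4, 12))
            scores = rng.permutation(np.arange(n)).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            _, pts = roc_points(scores, labels)
            trap = np.trapezoid(pts[:, 1], pts[:, 0])
            assert auc_mann_whitney(scores, labels) == pytest.approx(trap)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_mann_whitney([1, 2], [1, 1])


class TestOperatingPoint:
    @pytest.mark.parametrize(
        "sens,spec,lr_plus,inv_lr_minus",
        [
            (0.97, 0.79, 4.619, 26.33),
            (0.939, 0.871, 7.279, 14.28),
            (0.5, 0.5, 1.0, 1.0),
        ],
    )
    def test_likelihood_ratio_arithmetic(self, sens, spec, lr_plus, inv_lr_minus):
        lp, ilm = likelihood_ratios(sens, spec)
        assert lp == pytest.approx(lr_plus, abs=5e-4)
        assert ilm == pytest.approx(inv_lr_minus, abs=5e-3)

    def test_youden_point_on_known_configuration(self):
        # pos: 2,3,4 ; neg: 0,1,2 -> threshold 3 gives sens 2/3, spec 1.
        scores = [2.0, 3.0, 4.0, 0.0, 1.0, 2.0]
        labels = [1, 1, 1, 0, 0, 0]
        d = optimise_operating_point(scores, labels)
        assert d.sensitivity == pytest.approx(2 / 3)
        assert d.specificity == pytest.approx(1.0)
        assert d.accuracy == pytest.approx(5 / 6)
        assert np.isinf(d.lr_plus)

    def test_ties_resolve_toward_higher_specificity(self):
        # J = 0.5 at both threshold 4 (sens .5, spec 1) and threshold 1
        # (sens 1, spec .5); the higher-specificity point wins.
        scores = [4.0, 1.0, 3.0, 0.0]
        labels = [1, 1, 0, 0]
        d = optimise_operating_point(scores, labels)
        assert d.optimal_threshold == pytest.approx(4.0)
        assert d.specificity == pytest.approx(1.0)
        assert d.sensitivity == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        labels[:3] = 1
        labels[-3:] = 0
        d1 = optimise_operating_point(scores, labels)
        d2 = optimise_operating_point(np.exp(scores), labels)
        assert d1.auc == pytest.approx(d2.auc)
        assert d1.sensitivity == pytest.approx(d2.sensitivity)
        assert d1.specificity == pytest.approx(d2.specificity)


class TestStepwiseLogistic:
    def test_single_binary_predictor_matches_cross_product_ratio(self):
        # Exposure counts (19 of 61) vs (1 of 35): OR = 19*34 / (42*1).
        x = np.array([1] * 19 + [0] * 42 + [1] * 1 + [0] * 34)
        y = np.array([1] * 61 + [0] * 35)
        table = pd.DataFrame({"iph": x})
        fit = stepwise_logistic(table, y, ["iph"])
        assert fit.selected_variables == ["iph"]
        expected = 19 * 34 / (42 * 1)
        assert fit.odds_ratios["iph"][0] == pytest.approx(expected, rel=1e-6)
        assert fit.odds_ratios["iph"][1] <= expected <= fit.odds_ratios["iph"][2]

    def test_pure_noise_rarely_selects(self):
        rng = np.random.default_rng(4)
        empty = 0
        reps = 40
        for _ in range(reps):
            y = rng.integers(0, 2, size=500)
            table = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
            fit = stepwise_logistic(table, y, ["a", "b"])
            empty += not fit.selected_variables
        assert empty / reps >= 0.8

    def test_duplicated_candidate_does_not_change_fit(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 2, size=200)
        x = y * 1.0 + rng.normal(size=200)
        table = pd.DataFrame({"x": x, "x_copy": x.copy()})
        fit1 = stepwise_logistic(table[["x"]], y, ["x"])
        fit2 = stepwise_logistic(table, y, ["x", "x_copy"])
        assert fit1.selected_variables == fit2.selected_variables == ["x"]
        assert fit1.odds_ratios["x"][0] == pytest.approx(fit2.odds_ratios["x"][0])

    def test_constant_candidate_rejected(self):
        y = np.array([0, 1] * 10)
        table = pd.DataFrame({"c": np.ones(20)})
        with pytest.raises(ValueError):
            stepwise_logistic(table, y, ["c"])


class TestFeatureSelection:
    def test_both_gates_must_pass(self):
        rng = np.random.default_rng(6)
        n = 2000
        y = np.repeat([1, 0], n // 2)
        strong = y * 1.0 + rng.normal(size=n)  # AUC ~ 0.76
        weak = y * 0.25 + rng.normal(size=n)  # p tiny at n=2000 but AUC ~ 0.57
        table = pd.DataFrame({"strong": strong, "weak": weak})
        selected = select_radiomic_features(table, y)
        assert "strong" in selected
        assert "weak" not in selected

    def test_symmetric_auc_gate(self):
        rng = np.random.default_rng(7)
        n = 400
        y = np.repeat([1, 0], n // 2)
        inverted = -(y * 1.0) + rng.normal(size=n)  # AUC ~ 0.24 -> symmetrised 0.76
        table = pd.DataFrame({"inv": inverted})
        assert select_radiomic_features(table, y) == ["inv"]

    def test_constant_feature_skipped_and_empty_allowed(self):
        y = np.repeat([1, 0], 30)
        table = pd.DataFrame({"const": np.ones(60)})
        assert select_radiomic_features(table, y) == []


class TestDeLong:
    def test_identical_models_degenerate(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, size=40)
        y[:2] = 1
        y[-2:] = 0
        a1, a2, z, p = delong_test(s, s, y)
        assert a1 == pytest.approx(a2)
        assert z == 0.0
        assert p == 1.0

    def test_label_swap_antisymmetry(self):
        rng = np.random.default_rng(10)
        s1 = rng.normal(size=60)
        s2 = s1 * 0.5 + rng.normal(size=60)
        y = rng.integers(0, 2, size=60)
        y[:3] = 1
        y[-3:] = 0
        a1, a2, z, p = delong_test(s1, s2, y)
        b1, b2, z2, p2 = delong_test(s1, s2, 1 - y)
        assert b1 == pytest.approx(1 - a1)
        assert b2 == pytest.approx(1 - a2)
        assert abs(z2) == pytest.approx(abs(z))
        assert p2 == pytest.approx(p)

    def test_monotone_transform_leaves_z_unchanged(self):
        rng = np.random.default_rng(11)
        s1 = rng.normal(size=50)
        s2 = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[:3] = 1
        y[-3:] = 0
        _, _, z, _ = delong_test(s1, s2, y)
        _, _, z2, _ = delong_test(np.tanh(s1) * 10 + 3, s2, y)
        assert z2 == pytest.approx(z)


class TestBenjaminiHochberg:
    def test_adjustment_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        from plaque_radiomics.stats import benjamini_hochberg

        rng = np.random.default_rng(12)
        p = rng.uniform(size=30)
        mine = benjamini_hochberg(p)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(mine, expected)

    def test_fdr_gate_is_more_conservative(self):
        from plaque_radiomics.stats import select_radiomic_features

        rng = np.random.default_rng(13)
        n = 200
        y = np.repeat([1, 0], n // 2)
        cols = {f"f{i}": rng.normal(size=n) for i in range(20)}
        cols["signal"] = y * 1.2 + rng.normal(size=n)
        table = pd.DataFrame(cols)
        plain = set(select_radiomic_features(table, y))
        fdr = set(select_radiomic_features(table, y, fdr_correction=True))
        assert fdr <= plain
        assert "signal" in fdr
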