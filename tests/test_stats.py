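"""Tests for AUC, bootstrap CI, correlation screen, model selection and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonalysis.errors import InvalidLabels, RankDeficient
from phonalysis.stats import (
    auc_scalar,
    bootstrap_auc_ci,
    correlation_screen,
    descriptive_table,
    ols_aic_select,
    one_way_anova,
)


def brute_force_auc(pos, neg):
    """Pair-counting oracle: wins + half ties over all (pos, neg) pairs."""
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(1.0 for p in pos for n in neg if p == n)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAucScalar:
    def test_worked_example(self):
        # controls [2,3,4] vs cases [1,2,3]: 7 of 9 pairs favor controls
        values = np.array([2, 3, 4, 1, 2, 3], dtype=float)
        labels = np.array(["control"] * 3 + ["case"] * 3)
        auc = auc_scalar(values, labels, positive_label="case", direction="positive_lower")
        assert auc == pytest.approx(7 / 9)

    def test_perfect_separation(self):
        values = np.array([1.0, 2.0, 10.0, 11.0])
        labels = np.array(["a", "a", "b", "b"])
        assert auc_scalar(values, labels, "b") == 1.0

    def test_all_ties(self):
        values = np.ones(8)
        labels = np.array(["a", "b"] * 4)
        assert auc_scalar(values, labels, "b") == 0.5

    def test_matches_pair_counting_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n_pos = rng.integers(1, 21)
            n_neg = rng.integers(1, 21)
            pos = rng.integers(0, 6, n_pos).astype(float)  # discrete -> ties
            neg = rng.integers(0, 6, n_neg).astype(float)
            values = np.concatenate([pos, neg])
            labels = np.array([1] * n_pos + [0] * n_neg)
            assert auc_scalar(values, labels, 1) == pytest.approx(
                brute_force_auc(pos, neg), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        values = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[0], labels[1] = 0, 1
        assert auc_scalar(values, labels, 1) == pytest.approx(
            roc_auc_score(labels, values), abs=1e-12
        )

    @given(
        st.lists(st.integers(0, 9), min_size=1, max_size=15),
        st.lists(st.integers(0, 9), min_size=1, max_size=15),
    )
    @settings(deadline=None, max_examples=100)
    def test_label_flip_symmetry(self, pos, neg):
        values = np.array(pos + neg, dtype=float)
        labels = np.array([1] * len(pos) + [0] * len(neg))
        a = auc_scalar(values, labels, 1)
        b = auc_scalar(values, 1 - labels, 1)
        assert a + b == pytest.approx(1.0)

    def test_one_class_rejected(self):
        with pytest.raises(InvalidLabels):
            auc_scalar(np.ones(5), np.ones(5), positive_label=1)


class TestBootstrap:
    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
        labels = np.array([1] * 30 + [0] * 30)
        r = bootstrap_auc_ci(values, labels, 1, n_boot=500, seed=3)
        assert r.ci_low <= r.auc <= r.ci_high
        assert 0.0 <= r.ci_low and r.ci_high <= 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 20)])
        labels = np.array([1] * 20 + [0] * 20)
        a = bootstrap_auc_ci(values, labels, 1, n_boot=300, seed=5)
        b = bootstrap_auc_ci(values, labels, 1, n_boot=300, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_all_ties_ci_collapses_to_half(self):
        values = np.full(40, 2.0)
        labels = np.array([1, 0] * 20)
        r = bootstrap_auc_ci(values, labels, 1, n_boot=300, seed=1)
        assert r.ci_high - r.ci_low < 0.05
        assert r.auc == 0.5

    def test_small_class_warns(self):
        values = np.arange(8.0)
        labels = np.array([1] * 3 + [0] * 5)
        with pytest.warns(UserWarning):
            bootstrap_auc_ci(values, labels, 1, n_boot=50, seed=0)


class TestCorrelationScreen:
    @pytest.fixture()
    def table(self):
        rng = np.random.default_rng(3)
        n = 200
        mfcc2 = rng.normal(100, 15, n)
        return pd.DataFrame(
            {
                "mfcc_mn_2": mfcc2,
                "linear_feature": 2 * mfcc2 + 1,
                "monotone_feature": np.exp(mfcc2 / 30.0),
                "noise_feature": rng.normal(size=n),
            }
        )

    def test_linear_feature_retained_pearson(self, table):
        out = correlation_screen(
            table, ["mfcc_mn_2"], ["linear_feature", "noise_feature"], method="pearson"
        )
        assert out.loc["linear_feature", "mfcc_mn_2"] == pytest.approx(1.0)
        assert "noise_feature" not in out.index

    def test_monotone_feature_spearman_one(self, table):
        out = correlation_screen(
            table, ["mfcc_mn_2"], ["monotone_feature"], method="spearman"
        )
        assert out.loc["monotone_feature", "mfcc_mn_2"] == pytest.approx(1.0)

    def test_constant_column_zeroed_with_warning(self, table):
        table = table.assign(const=1.0)
        with pytest.warns(UserWarning, match="constant"):
            out = correlation_screen(table, ["mfcc_mn_2"], ["const", "linear_feature"])
        assert "const" not in out.index


class TestModelSelection:
    def test_recovers_injected_sex_effect(self):
        rng = np.random.default_rng(4)
        n = 400
        sex = rng.choice(["male", "female"], n)
        age = rng.uniform(40, 80, n)
        y = 10.0 + 5.0 * (sex == "male") + rng.normal(0, 1, n)
        table = pd.DataFrame({"y": y, "sex": sex, "age": age})
        best, _ = ols_aic_select(table, "y", ["sex", "age"])
        assert "sex" in best.factors
        assert 4.0 <= best.coefficients["sex_male"] <= 6.0

    def test_pure_noise_prefers_intercept_only(self):
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(50):
            table = pd.DataFrame(
                {"y": rng.normal(size=100), "x": rng.normal(size=100)}
            )
            best, _ = ols_aic_select(table, "y", ["x"])
            hits += best.factors == ()
        assert hits >= 0.7 * 50  # AIC admits a spurious factor ~16% of the time

    def test_duplicated_factor_rank_deficient(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        table = pd.DataFrame({"y": rng.normal(size=50), "x1": x, "x2": x})
        with pytest.raises(RankDeficient):
            ols_aic_select(table, "y", ["x1", "x2"], candidate_sets=[("x1", "x2")])

    def test_aic_formula(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame({"y": rng.normal(size=60), "x": rng.normal(size=60)})
        _, fits = ols_aic_select(table, "y", ["x"])
        for fit in fits:
            p = 1 + len([f for f in fit.factors])
            expected = fit.n * np.log(fit.rss / fit.n) + 2 * (p + 1)
            assert fit.aic == pytest.approx(expected)


class TestAnova:
    def test_identical_groups_zero_f(self):
        g = np.array([1.0, 2.0, 3.0])
        f, p = one_way_anova([g, g.copy(), g.copy()])
        assert f == 0.0 and p == 1.0

    def test_separated_groups_tiny_p(self):
        rng = np.random.default_rng(8)
        f, p = one_way_anova([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        assert p < 1e-6

    def test_matches_scipy(self):
        import scipy.stats

        rng = np.random.default_rng(9)
        groups = [rng.normal(0, 1, 20), rng.normal(0.5, 1, 25), rng.normal(1, 2, 15)]
        f, p = one_way_anova(groups)
        f2, p2 = scipy.stats.f_oneway(*groups)
        assert f == pytest.approx(f2) and p == pytest.approx(p2)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([np.array([1.0, 2.0])])


class TestDescriptiveTable:
    def test_single_row_cells_have_zero_sd(self):
        table = pd.DataFrame(
            {"sex": ["m", "f"], "group": ["a", "a"], "x": [1.0, 2.0]}
        )
        out = descriptive_table(table, ["x"], by=["sex", "group"])
        assert (out["x_sd"] == 0).all()
        assert (out["n"] == 1).all()

    def test_column_shape(self):
        rng = np.random.default_rng(10)
        table = pd.DataFrame(
            {
                "sex": rng.choice(["m", "f"], 40),
                "group": rng.choice(["a", "b"], 40),
                "x": rng.normal(size=40),
                "y": rng.normal(size=40),
            }
        )
        out = descriptive_table(table, ["x", "y"], by=["sex", "group"])
        assert out.shape[1] == 2 * 2 + 2 + 1  # metrics x 2 + grouping + n

    def test_empty_cell_warns(self):
        table = pd.DataFrame(
            {"sex": ["m", "m", "f"], "group": ["a", "b", "a"], "x": [1.0, 2.0, 3.0]}
        )
        with pytest.warns(UserWarning, match="empty"):
            out = descriptive_table(table, ["x"], by=["sex", "group"])
        assert len(out) == 3
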