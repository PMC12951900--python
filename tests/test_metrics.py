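"""Evaluation statistics: AUC pair-counting, DeLong (with a frozen pROC
cross-check), horizon AUC, NRI identities, optimism correction, region CV
and the heterogeneity Z-test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import score2pro as sp
from score2pro.metrics import delong_variance

from conftest import binary_fixture


class TestAuc:
    def test_pair_counting(self):
        assert sp.auc([3, 1, 2, 0], [1, 1, 0, 0]) == 0.75

    def test_perfect_and_ties(self):
        y = np.array([0, 1, 0, 1])
        assert sp.auc(y.astype(float), y) == 1.0
        assert sp.auc(np.ones(4), y) == 0.5

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=200)
        y = (rng.random(200) < 0.4).astype(int)
        assert sp.auc(s, y) == pytest.approx(1 - sp.auc(s, 1 - y), abs=0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sp.auc([1.0, 2.0], [1, 1])


class TestDeLong:
    @staticmethod
    def _fixture():
        # regenerates the fixture frozen against R pROC (roc.test, DeLong)
        rng = np.random.default_rng(2024)
        n1, n0 = 60, 140
        base = np.concatenate([rng.normal(0.9, 1, n1),
                               rng.normal(0.0, 1, n0)])
        e1 = rng.normal(0, 0.6, n1 + n0)
        e2 = rng.normal(0, 0.6, n1 + n0)
        y = np.array([1] * n1 + [0] * n0)
        return base + e1, 0.8 * base + e2, y

    def test_matches_pROC_frozen_values(self):
        sa, sb, y = self._fixture()
        c = sp.delong_compare(sa, sb, y)
        assert c.auc_a == pytest.approx(0.7713095238, abs=1e-9)
        assert c.auc_b == pytest.approx(0.7386904762, abs=1e-9)
        assert abs(c.z) == pytest.approx(1.0159191548, abs=1e-8)
        assert c.p == pytest.approx(0.3096678865, abs=1e-8)
        assert delong_variance(sa, y)[1] == pytest.approx(
            1.3043946752e-03, rel=1e-8)

    def test_self_comparison_degenerate(self):
        sa, _, y = self._fixture()
        c = sp.delong_compare(sa, sa, y)
        assert c.degenerate and c.delta == 0.0 and c.p == 1.0

    def test_symmetry(self):
        sa, sb, y = self._fixture()
        ab = sp.delong_compare(sa, sb, y)
        ba = sp.delong_compare(sb, sa, y)
        assert ab.p == ba.p
        assert ab.delta == -ba.delta
        assert ab.var_a == ba.var_b and ab.cov_ab == ba.cov_ab


class TestDynamicAuc:
    def test_reduces_to_plain_auc_without_censoring(self):
        rng = np.random.default_rng(3)
        n = 300
        s = rng.normal(size=n)
        t = rng.uniform(0, 10, size=n)
        e = (rng.random(n) < 0.5).astype(int)
        t[e == 0] = 10.0  # censoring only at the maximal horizon
        out = sp.dynamic_auc(s, t, e, [10.0])
        assert out["auc"].iloc[0] == pytest.approx(sp.auc(s, e), abs=0)

    def test_earlier_events_scored_higher_gives_one(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 0, 0, 0])
        s = -t
        out = sp.dynamic_auc(s, t, e, [1.5, 2.5, 3.5])
        assert np.all(out["auc"].to_numpy() == 1.0)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(4)
        n = 2000
        s = rng.normal(size=n)
        t = rng.exponential(8, size=n)
        e = (t < 10).astype(int)
        t = np.minimum(t, 10)
        out = sp.dynamic_auc(s, t, e, [2.0, 5.0, 8.0])
        assert out["n_cases"].min() >= 50
        assert np.all((out["auc"] > 0.4) & (out["auc"] < 0.6))

    def test_missing_class_gives_nan(self):
        out = sp.dynamic_auc([1.0, 2.0], [5.0, 6.0], [0, 0], [1.0])
        assert np.isnan(out["auc"].iloc[0])


class TestCategoricalNri:
    def test_identity_when_unchanged(self):
        rng = np.random.default_rng(5)
        r = rng.random(200)
        y = (rng.random(200) < 0.3).astype(int)
        res = sp.categorical_nri(r, r, y, 0.5, n_boot=50, seed=0)
        assert res.nri_overall == 0 == res.nri_event == res.nri_nonevent
        for tab in res.counts.values():
            assert tab[0][1] == 0 and tab[1][0] == 0

    def test_formula_on_counts(self):
        # events: 10 up, 5 down of 50; non-events: 20 down, 10 up of 200
        y = np.r_[np.ones(50), np.zeros(200)].astype(int)
        old = np.zeros(250)
        new = np.zeros(250)
        thr = 0.5
        old[:50] = np.r_[np.full(10, 0.4), np.full(5, 0.6), np.full(35, 0.4)]
        new[:50] = np.r_[np.full(10, 0.6), np.full(5, 0.4), np.full(35, 0.4)]
        old[50:] = np.r_[np.full(20, 0.6), np.full(10, 0.4), np.full(170, 0.4)]
        new[50:] = np.r_[np.full(20, 0.4), np.full(10, 0.6), np.full(170, 0.4)]
        res = sp.categorical_nri(old, new, y, thr, n_boot=50, seed=0)
        assert res.nri_event == pytest.approx(0.10)
        assert res.nri_nonevent == pytest.approx(0.05)
        assert res.nri_overall == pytest.approx(0.15)
        assert res.counts["event"][0][1] == 10  # low -> high movers

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_overall_identity_machine_precision(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0], y[1] = 0, 1
        old = rng.random(n)
        new = rng.random(n)
        res = sp.categorical_nri(old, new, y, float(rng.uniform(0.1, 0.9)),
                                 n_boot=10, seed=0)
        assert res.nri_overall == res.nri_event + res.nri_nonevent

    def test_input_validation(self):
        y = np.array([0, 1, 0, 1])
        with pytest.raises(ValueError):
            sp.categorical_nri([0.1, 0.2, 1.5, 0.3], [0.1] * 4, y, 0.5)
        with pytest.raises(ValueError):
            sp.categorical_nri([0.1] * 4, [0.1] * 4, np.zeros(4, int), 0.5)


def test_calibrate_risks_preserves_order_and_range():
    rng = np.random.default_rng(6)
    risk = rng.random(500) * 0.5
    y = (rng.random(500) < risk).astype(int)
    out = sp.calibrate_risks(risk, y, np.sort(risk))
    assert np.all((out >= 0) & (out <= 1))
    assert np.all(np.diff(out) >= -1e-12)


class TestOptimism:
    def test_constant_recipe_no_optimism(self):
        X, y = binary_fixture(7, n=300)

        def fit_predict(Xtr, ytr, Xev):
            return np.full(len(Xev), 0.5)

        out = sp.optimism_corrected_auc(X, y, fit_predict, n_boot=30, seed=0)
        assert out["apparent_auc"] == pytest.approx(0.5, abs=1e-12)
        assert abs(out["mean_optimism"]) < 1e-12

    def test_single_resample_warns(self):
        X, y = binary_fixture(8, n=100)

        def fit_predict(Xtr, ytr, Xev):
            return Xev[:, 0]

        with pytest.warns(UserWarning, match="unstable"):
            sp.optimism_corrected_auc(X, y, fit_predict, n_boot=1, seed=0)


class TestRegionCv:
    @staticmethod
    def _fit_predict(Xtr, ytr, Xev):
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(max_iter=200).fit(Xtr, ytr)
        return lr.predict_proba(Xev)[:, 1]

    def test_two_regions_two_folds(self):
        X, y = binary_fixture(9, n=400)
        regions = np.r_[np.zeros(200), np.ones(200)]
        out = sp.region_cv(X, y, regions, self._fit_predict)
        assert out["n_folds"] == 2

    def test_null_regions_center_on_half(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((2000, 3))
        y = (rng.random(2000) < 0.3).astype(int)
        regions = rng.integers(0, 10, 2000)
        out = sp.region_cv(X, y, regions, self._fit_predict)
        assert 0.45 < out["mean_auc"] < 0.55

    def test_single_class_fold_skipped(self):
        X, y = binary_fixture(11, n=200)
        regions = np.r_[np.zeros(100), np.ones(95), np.full(5, 2.0)]
        y[195:] = 0  # region 2's test fold has a single class
        with pytest.warns(UserWarning, match="skipped"):
            out = sp.region_cv(X, y, regions, self._fit_predict)
        assert out["n_folds"] == 2


class TestHeterogeneityZ:
    def test_equal_gives_null(self):
        z, p = sp.hr_heterogeneity_z(0.3, 0.1, 0.3, 0.2)
        assert z == 0.0 and p == 1.0

    def test_closed_form_example(self):
        z, p = sp.hr_heterogeneity_z(np.log(2), 0.2, 0.0, 0.2)
        assert z == pytest.approx(2.4507, abs=1e-3)
        assert p == pytest.approx(0.0143, abs=2e-4)

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            sp.hr_heterogeneity_z(0.1, 0.0, 0.2, 0.1)
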