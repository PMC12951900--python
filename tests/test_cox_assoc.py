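"""Cox screening: partial-likelihood oracle checks, lifelines cross-check,
Bonferroni control plumbing, Youden cutoffs and dichotomized survival."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import kstest

import score2pro as sp
from score2pro.cox_assoc import (CoxError, cox_partial_fit,
                                 cox_partial_loglik, covariate_matrix,
                                 screen_table, _km_curve)


def grid_max_loglik(time, event, x):
    """Independent oracle: golden-section maximization of the written
    partial likelihood over a single coefficient."""
    res = minimize_scalar(
        lambda b: -cox_partial_loglik(time, event, x[:, None], np.array([b])),
        bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10})
    return float(res.x)


def test_three_subject_closed_form():
    # partial likelihood e^b/(2e^b+1) * 1/(1+e^b) maximized at b = -ln(2)/2
    t = np.array([1.0, 2.0, 3.0])
    e = np.array([1.0, 1.0, 0.0])
    x = np.array([1.0, 0.0, 1.0])
    r = sp.fit_cox(t, e, x)
    assert abs(r.log_hr - (-0.5 * np.log(2.0))) < 1e-6


@pytest.mark.parametrize("seed", range(6))
def test_fit_matches_grid_oracle_on_tiny_fixtures(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    t = np.round(rng.exponential(5, n), 1) + 0.1  # rounding creates ties
    e = (rng.random(n) < 0.7).astype(float)
    if e.sum() < 2:
        e[:2] = 1.0
    x = rng.standard_normal(n)
    if np.ptp(x) == 0:
        x[0] += 1.0
    beta, _, _, conv = cox_partial_fit(t, e, x[:, None])
    if not conv:
        pytest.skip("monotone likelihood on this draw")
    assert abs(beta[0] - grid_max_loglik(t, e, x)) < 1e-4


def test_matches_lifelines_with_ties():
    from lifelines import CoxPHFitter
    rng = np.random.default_rng(42)
    n = 400
    X = rng.standard_normal((n, 3))
    t = np.ceil(rng.exponential(10, n))  # heavy ties
    e = (rng.random(n) < 0.5).astype(float)
    beta, cov, _, _ = cox_partial_fit(t, e, X)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    df["t"], df["e"] = t, e
    cph = CoxPHFitter()
    cph.fit(df, "t", "e")
    assert np.allclose(beta, cph.params_.to_numpy(), atol=1e-5)
    assert np.allclose(np.sqrt(np.diag(cov)),
                       cph.standard_errors_.to_numpy(), atol=1e-5)


def test_degenerate_inputs_rejected():
    t = np.arange(1.0, 7.0)
    e = np.array([1, 1, 0, 1, 0, 1.0])
    with pytest.raises(CoxError):
        sp.fit_cox(t, e, np.ones(6))  # constant exposure
    with pytest.raises(CoxError):
        sp.fit_cox(t, np.zeros(6), np.arange(6.0))  # < 2 events


def test_monotone_likelihood_flagged():
    # exposure perfectly ordered with event times: likelihood is monotone
    t = np.arange(1.0, 11.0)
    e = np.ones(10)
    x = -np.arange(10.0)
    r = sp.fit_cox(t, e, x)
    assert not r.converged


def test_per_sd_convention_affine_invariance():
    rng = np.random.default_rng(0)
    n = 1500
    x = rng.standard_normal(n)
    t = 50 * np.exp(-0.5 * x) * rng.exponential(1, n)
    e = (t < 30).astype(float)
    t = np.minimum(t, 30)
    r1 = sp.fit_cox(t, e, x)
    r2 = sp.fit_cox(t, e, 2.0 * x)
    assert abs(r2.log_hr - r1.log_hr / 2) < 1e-8
    # rescaling to unit SD restores the per-SD log-HR
    r3 = sp.fit_cox(t, e, (2.0 * x) / np.std(2.0 * x))
    assert abs(r3.log_hr - r1.log_hr * np.std(x)) < 1e-8


class TestScreen:
    def test_alpha_zero_nothing_significant(self, null_cohort):
        res = sp.screen_proteins(null_cohort, alpha=0.0,
                                 rows=null_cohort.derivation_mask())
        assert not any(r.significant_bonferroni for r in res)

    def test_null_pvalues_uniform(self, null_cohort):
        res = sp.screen_proteins(null_cohort,
                                 rows=null_cohort.derivation_mask())
        pvals = np.array([r.p for r in res if r.converged])
        assert kstest(pvals, "uniform").pvalue > 0.001

    def test_table_and_threshold(self, small_cohort):
        prepared = small_cohort["prepared"]
        res = sp.screen_proteins(prepared, rows=prepared.derivation_mask())
        tab = screen_table(res)
        assert len(tab) == len(prepared.protein_cols)
        thresh = 0.05 / len(prepared.protein_cols)
        agree = (tab["p"] < thresh) == tab["significant"]
        assert agree[tab["converged"]].all()
        # planted general effects are recovered
        sig = set(tab.loc[tab["significant"].astype(bool), "protein"])
        assert {"prot_0000", "prot_0001"} <= sig


class TestYouden:
    def test_perfect_separation(self):
        marker = np.array([2.0, 3.0, 0.0, 1.0])
        event = np.array([1, 1, 0, 0])
        assert sp.youden_cutoff(marker, event) == 2.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        marker = rng.normal(size=300)
        event = (rng.random(300) < 0.3).astype(int)
        cut = sp.youden_cutoff(marker, event)

        def j_at(t):
            sens = np.mean(marker[event == 1] >= t)
            spec = np.mean(marker[event == 0] < t)
            return sens + spec - 1

        best = max(j_at(t) for t in np.unique(marker))
        assert abs(j_at(cut) - best) < 1e-12

    def test_tie_broken_low(self):
        # two cutoffs reach J = 1; the smaller one must be returned
        marker = np.array([0.0, 1.0, 2.0, 3.0])
        event = np.array([0, 0, 1, 1])
        assert sp.youden_cutoff(marker, event) == 2.0

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError):
            sp.youden_cutoff(np.ones(10), np.r_[np.ones(5), np.zeros(5)])


class TestKaplanMeier:
    def test_no_events_curve_is_one(self):
        tab = _km_curve(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert np.all(tab["survival"].to_numpy() == 1.0)

    def test_product_limit_hand_computation(self):
        # 6 subjects: events at 1, 2, 4; censored at 3, 5, 6
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 0, 0])
        tab = _km_curve(t, e).set_index("time")["survival"]
        assert np.isclose(tab.loc[1.0], 5 / 6)
        assert np.isclose(tab.loc[2.0], 5 / 6 * 4 / 5)
        assert np.isclose(tab.loc[4.0], 5 / 6 * 4 / 5 * 2 / 3)

    def test_joint_grouping_risk_ordering(self):
        # harmful protein A, protective protein B: the A-high/B-low group
        # must carry the largest adjusted HR of the four
        cfg = sp.SimConfig(n_participants=6000, n_proteins=2, seed=13,
                           effects=(sp.PlantedEffect(0, 0.8),
                                    sp.PlantedEffect(1, -0.8)))
        c = sp.simulate_cohort(cfg)
        out = sp.km_dichotomized_analysis(c, ["prot_0000", "prot_0001"])
        assert out["reference"] == "prot_0000_low|prot_0001_high"
        hrs = {g: r.hr for g, r in out["hr_vs_reference"].items()}
        assert max(hrs, key=hrs.get) == "prot_0000_high|prot_0001_low"
        assert len(out["km_curves"]) == 4

    def test_follow_up_capped(self):
        cfg = sp.SimConfig(n_participants=800, n_proteins=1, seed=14,
                           admin_censor_years=20.0)
        c = sp.simulate_cohort(cfg)
        out = sp.km_dichotomized_analysis(c, ["prot_0000"], cap_years=15.0)
        for tab in out["km_curves"].values():
            assert tab["time"].max() <= 15.0
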