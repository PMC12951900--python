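"""Preparation contracts: the missingness filter, imputation, derived
variables with leakage-frozen scaling, and the derivation/validation split."""

import numpy as np
import pandas as pd
import pytest

import score2pro as sp
from score2pro.synthetic_cohort import Cohort, protein_name


def _toy_cohort(missing_fracs, n_rows=100):
    """A cohort whose proteins have exactly the requested missing counts."""
    rng = np.random.default_rng(0)
    cols = {}
    prot_cols = []
    for i, f in enumerate(missing_fracs):
        name = protein_name(i)
        x = rng.standard_normal(n_rows)
        k = int(round(f * n_rows))
        if k:
            x[:k] = np.nan
        cols[name] = x
        prot_cols.append(name)
    df = pd.DataFrame(cols)
    df["follow_time"] = 1.0
    df["event"] = 0
    df["split"] = "unassigned"
    return Cohort(df, prot_cols)


class TestFilterProteins:
    def test_threshold_rule(self):
        c = _toy_cohort([0.0, 0.24, 0.26, 0.50])
        out, report = sp.filter_proteins(c, 0.25)
        assert out.protein_cols == [protein_name(0), protein_name(1)]
        assert sorted(report["protein"]) == [protein_name(2), protein_name(3)]

    def test_paper_scale_filter(self):
        # 2,923 proteins of which exactly 4 exceed 25% missingness
        fracs = [0.0] * 2919 + [0.3, 0.4, 0.5, 0.9]
        c = _toy_cohort(fracs, n_rows=20)
        out, report = sp.filter_proteins(c, 0.25)
        assert len(out.protein_cols) == 2919
        assert len(report) == 4

    def test_loose_threshold_keeps_everything(self):
        c = _toy_cohort([0.0, 0.5, 0.99])
        out, _ = sp.filter_proteins(c, 0.9999)
        assert len(out.protein_cols) == 3

    def test_all_dropped_is_error(self):
        c = _toy_cohort([0.9, 0.95])
        with pytest.raises(ValueError):
            sp.filter_proteins(c, 0.25)


class TestImputeClinical:
    def test_no_missing_identity(self, small_cohort):
        cfg = sp.SimConfig(n_participants=300, n_proteins=2, seed=1)
        c = sp.simulate_cohort(cfg)
        out = sp.impute_clinical(c, "median", seed=0)
        pd.testing.assert_frame_equal(out.data, c.data)

    def test_median_fills_with_observed_median(self):
        cfg = sp.SimConfig(n_participants=400, n_proteins=2, seed=2)
        c = sp.simulate_cohort(cfg)
        mask = np.zeros(400, dtype=bool)
        mask[:40] = True
        observed_median = c.data.loc[~mask, "sbp"].median()
        c.data.loc[mask, "sbp"] = np.nan
        out = sp.impute_clinical(c, "median", seed=0)
        assert np.allclose(out.data.loc[mask, "sbp"], observed_median)
        # observed entries untouched
        assert np.array_equal(out.data.loc[~mask, "sbp"],
                              c.data.loc[~mask, "sbp"])

    def test_forest_beats_median_on_mcar(self):
        # SBP correlates with DBP and total cholesterol with the lipids,
        # so chained forest imputation must beat the marginal median
        cfg = sp.SimConfig(n_participants=1500, n_proteins=1, seed=3)
        c = sp.simulate_cohort(cfg)
        rng = np.random.default_rng(4)
        truth = {}
        masked = c.copy()
        for col in ("sbp", "total_chol"):
            m = rng.random(len(c)) < 0.10
            truth[col] = (m, c.data[col].to_numpy().copy())
            masked.data.loc[m, col] = np.nan
        med = sp.impute_clinical(masked, "median", seed=5)
        forest = sp.impute_clinical(masked, "iterative_forest", seed=5)

        def rmse(out, col):
            m, orig = truth[col]
            return float(np.sqrt(np.mean(
                (out.data.loc[m, col].to_numpy() - orig[m]) ** 2)))

        for col in ("sbp", "total_chol"):
            assert rmse(forest, col) <= rmse(med, col), col

    def test_forest_deterministic(self):
        cfg = sp.SimConfig(n_participants=400, n_proteins=1, seed=6,
                           missing_rate_clinical=0.1)
        c = sp.apply_missingness(sp.simulate_cohort(cfg), cfg, seed=6)
        a = sp.impute_clinical(c, "iterative_forest", seed=9)
        b = sp.impute_clinical(c, "iterative_forest", seed=9)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_entirely_missing_column_is_error(self):
        cfg = sp.SimConfig(n_participants=100, n_proteins=1, seed=7)
        c = sp.simulate_cohort(cfg)
        c.data["crp"] = np.nan
        with pytest.raises(ValueError, match="crp"):
            sp.impute_clinical(c, "median", seed=0)


class TestDeriveVariables:
    def test_non_hdl_subtraction(self):
        cfg = sp.SimConfig(n_participants=50, n_proteins=1, seed=8)
        c = sp.simulate_cohort(cfg)
        c.data.loc[0, ["total_chol", "hdl"]] = [5.6, 1.4]
        out = sp.derive_variables(c, scale_proteins=False)
        assert np.isclose(out.data.loc[0, "non_hdl"], 4.2)

    def test_scaling_contract_on_derivation(self, small_cohort):
        prepared = small_cohort["prepared"]
        deriv = prepared.derivation_mask()
        block = prepared.data.loc[deriv, prepared.protein_cols]
        mu = block.mean(skipna=True)
        sd = block.std(ddof=0, skipna=True)
        assert np.all(np.abs(mu.to_numpy()) < 1e-8)
        assert np.all(np.abs(sd.to_numpy() - 1) < 1e-6)
        assert prepared.proteins_standardized

    def test_scaling_frozen_no_leakage(self):
        # shift validation rows: their post-scaling mean must be shift/sd,
        # proving the parameters came from derivation rows only
        cfg = sp.SimConfig(n_participants=2000, n_proteins=3, seed=9)
        c = sp.simulate_cohort(cfg)
        c = sp.split_cohort(c, 0.7, seed=9)
        val = c.data["split"] == "validation"
        shift = 1.7
        c.data.loc[val, "prot_0000"] += shift
        deriv = ~val
        deriv_mean = c.data.loc[deriv, "prot_0000"].mean()
        deriv_sd = c.data.loc[deriv, "prot_0000"].std(ddof=0)
        expected = (c.data.loc[val, "prot_0000"].mean() - deriv_mean) / deriv_sd
        out = sp.derive_variables(c)
        val_mean = out.data.loc[val, "prot_0000"].mean()
        assert abs(val_mean - expected) < 1e-10
        assert val_mean > 1.0  # clearly non-zero: parameters were frozen

    def test_hdl_above_total_rejected(self):
        cfg = sp.SimConfig(n_participants=100, n_proteins=1, seed=10)
        c = sp.simulate_cohort(cfg)
        c.data.loc[:10, "hdl"] = c.data.loc[:10, "total_chol"] + 1
        with pytest.raises(ValueError, match="hdl"):
            sp.derive_variables(c)


class TestSplit:
    def test_rounding_rule(self):
        cfg = sp.SimConfig(n_participants=10, n_proteins=1, seed=11)
        c = sp.split_cohort(sp.simulate_cohort(cfg), 0.7, seed=0)
        assert (c.data["split"] == "derivation").sum() == 7
        assert (c.data["split"] == "validation").sum() == 3

    def test_deterministic(self):
        cfg = sp.SimConfig(n_participants=200, n_proteins=1, seed=12)
        c = sp.simulate_cohort(cfg)
        a = sp.split_cohort(c, 0.7, seed=3).data["split"]
        b = sp.split_cohort(c, 0.7, seed=3).data["split"]
        assert (a == b).all()

    def test_paper_scale_count(self):
        df = pd.DataFrame({"follow_time": np.ones(51010), "event": 0,
                           "split": "unassigned"})
        c = Cohort(df, [])
        out = sp.split_cohort(c, 0.70, seed=1)
        assert (out.data["split"] == "derivation").sum() == 35707


def test_prepare_idempotent_and_preserves_outcomes(small_cohort):
    prepared = small_cohort["prepared"]
    cfg = sp.PrepConfig(imputation_method="median", split_seed=11)
    again, _ = sp.prepare(prepared, cfg)
    assert (again.data["split"] == prepared.data["split"]).all()
    assert np.allclose(again.data[again.protein_cols].to_numpy(dtype=float),
                       prepared.data[prepared.protein_cols].to_numpy(dtype=float),
                       atol=1e-10, equal_nan=True)
    raw = small_cohort["raw"]
    # no stage ever modifies outcomes
    assert np.array_equal(prepared.data["follow_time"].to_numpy(),
                          raw.data["follow_time"].to_numpy())
    assert np.array_equal(prepared.data["event"].to_numpy(),
                          raw.data["event"].to_numpy())
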