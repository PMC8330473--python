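"""Survival transforms, Cox/frailty fitting, model comparison, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from patchcamo import synth
from patchcamo.survival import (
    CoxFrailtyModel,
    aic_ladder,
    centre_distance_quartiles,
    field_response,
    lr_test,
    online_response,
)


class TestFieldResponse:
    @pytest.mark.parametrize(
        "d_detect,d_min,d_max,expect_resp,expect_event",
        [
            (60.0, 10.0, 60.0, 0.0, 1),  # spotted at first visibility
            (27.0, 10.0, 54.0, 0.5, 1),
            (np.nan, 10.0, 50.0, 0.8, 0),  # missed: closest-approach censoring
        ],
    )
    def test_examples(self, d_detect, d_min, d_max, expect_resp, expect_event):
        resp, ev = field_response([d_detect], [d_min], [d_max])
        assert np.isclose(resp[0], expect_resp)
        assert ev[0] == expect_event

    @given(st.floats(10.0, 60.0), st.floats(10.0, 60.0))
    def test_monotone_decreasing_in_distance(self, d1, d2):
        lo, hi = sorted((d1, d2))
        r_lo, _ = field_response([hi], [1.0], [60.0])
        r_hi, _ = field_response([lo], [1.0], [60.0])
        assert r_hi[0] >= r_lo[0]

    def test_censoring_below_any_closer_detection(self):
        """A missed target's response never exceeds the response of a
        detection closer than d_min at the same position."""
        cens, _ = field_response([np.nan], [10.0], [50.0])
        det, _ = field_response([5.0], [10.0], [50.0])
        assert cens[0] <= det[0]

    def test_errors(self):
        with pytest.raises(ValueError):
            field_response([70.0], [10.0], [60.0])
        with pytest.raises(ValueError):
            field_response([20.0], [60.0], [60.0])


class TestOnlineResponse:
    def test_examples(self):
        resp, ev = online_response([3.2, np.nan], timeout_s=10)
        assert np.allclose(resp, [3.2, 10.0])
        assert np.array_equal(ev, [1, 0])

    def test_time_above_timeout_raises(self):
        with pytest.raises(ValueError):
            online_response([11.0])

    def test_quartiles_of_eight(self):
        q = centre_distance_quartiles([1, 2, 3, 4, 5, 6, 7, 8])
        assert np.array_equal(q, [0, 0, 1, 1, 2, 2, 3, 3])

    def test_boundary_ties_go_low(self):
        d = np.array([1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        q = centre_distance_quartiles(d)
        assert q[0] == 0 and np.all(q[:4] == q[0])


def _sim_cox(rng, n=300, tied=False):
    X = np.c_[rng.integers(0, 2, n), rng.standard_normal(n)]
    eta = 0.7 * X[:, 0] - 0.3 * X[:, 1]
    t = rng.exponential(1 / np.exp(eta))
    c = rng.exponential(1.5, n)
    y = np.minimum(t, c)
    e = (t <= c).astype(int)
    if tied:
        y = np.round(y, 1) + 1e-6
    return y, e, X


class TestCoxAgainstReference:
    """Fixed-effects fits must agree with an independent partial-likelihood
    implementation (lifelines) to 1e-6 in beta."""

    @pytest.mark.parametrize("tied", [False, True])
    def test_matches_lifelines(self, rng, tied):
        lifelines = pytest.importorskip("lifelines")
        y, e, X = _sim_cox(rng, tied=tied)
        res = CoxFrailtyModel(y, e, X, ["g", "z"]).fit()
        df = pd.DataFrame({"T": y, "E": e, "g": X[:, 0], "z": X[:, 1]})
        ref = lifelines.CoxPHFitter().fit(df, "T", "E", fit_options={"precision": 1e-9})
        assert np.max(np.abs(res.params_ - ref.params_.values)) < 1e-6
        assert np.isclose(res.llf, ref.log_likelihood_, atol=1e-8)
        assert np.max(np.abs(res.bse.values - ref.standard_errors_.values)) < 1e-6

    def test_matches_lifelines_with_strata(self, rng):
        lifelines = pytest.importorskip("lifelines")
        y, e, X = _sim_cox(rng, n=400)
        strata = rng.integers(0, 3, 400)
        res = CoxFrailtyModel(y, e, X, ["g", "z"], strata=strata).fit()
        df = pd.DataFrame({"T": y, "E": e, "g": X[:, 0], "z": X[:, 1], "s": strata})
        ref = lifelines.CoxPHFitter().fit(df, "T", "E", strata=["s"],
                                          fit_options={"precision": 1e-9})
        assert np.max(np.abs(res.params_ - ref.params_.values)) < 1e-6


class TestCoxBehaviour:
    def test_hr_is_exp_beta(self, rng):
        y, e, X = _sim_cox(rng)
        res = CoxFrailtyModel(y, e, X, ["g", "z"]).fit()
        assert np.allclose(res.hazard_ratios.values, np.exp(res.params_))
        ci = res.conf_int()
        assert np.all(ci.hr_lower.values < res.hazard_ratios.values)
        assert np.all(res.hazard_ratios.values < ci.hr_upper.values)

    def test_two_group_hazard_ratio_recovered(self):
        """Group B with twice group A's hazard, n=4000: HR in [1.85, 2.15]."""
        rng = np.random.default_rng(77)
        n = 4000
        g = rng.integers(0, 2, n)
        t = rng.exponential(1 / np.exp(np.log(2.0) * g))
        res = CoxFrailtyModel(t, np.ones(n, int), g[:, None], ["g"]).fit()
        assert 1.85 <= float(res.hazard_ratios.iloc[0]) <= 2.15

    def test_no_events_raises(self):
        with pytest.raises(ValueError):
            CoxFrailtyModel([1.0, 2.0], [0, 0], [[1.0], [0.0]], ["x"])

    def test_frailty_shrinks_with_null_groups(self, rng):
        """With no real group structure the frailty variance estimate is
        near zero and fixed effects match the fixed-only fit closely."""
        y, e, X = _sim_cox(rng, n=400)
        groups = rng.integers(0, 20, 400)
        mixed = CoxFrailtyModel(y, e, X, ["g", "z"], frailty={"grp": groups}).fit()
        fixed = CoxFrailtyModel(y, e, X, ["g", "z"]).fit()
        assert mixed.frailty_variances["grp"] < 0.05
        assert np.max(np.abs(mixed.params_ - fixed.params_)) < 0.05

    def test_frailty_recovery_single_dataset(self):
        tr = synth.generate_detection_trials(synth.TrialDesign(seed=21))
        res = CoxFrailtyModel.from_dataframe(
            tr, ["strategy"], frailty=["subject", "position"]
        ).fit()
        ci = res.conf_int().iloc[0]
        assert ci.hr_lower < 0.5 < ci.hr_upper
        assert "strategy" in res.summary()

    def test_summary_mentions_frailty(self):
        tr = synth.generate_detection_trials(synth.TrialDesign(seed=2))
        res = CoxFrailtyModel.from_dataframe(
            tr, ["strategy"], frailty=["subject"]
        ).fit()
        assert "frailty" in res.summary()


class TestModelComparison:
    def _two_fits(self, rng):
        y, e, X = _sim_cox(rng, n=500)
        full = CoxFrailtyModel(y, e, X, ["g", "z"]).fit()
        reduced = CoxFrailtyModel(y, e, X[:, :1], ["g"]).fit()
        return full, reduced

    def test_lr_test_chi2_definition(self, rng):
        full, reduced = self._two_fits(rng)
        chi2, df, p = lr_test(full, reduced)
        assert df == 1
        assert np.isclose(chi2, 2 * (full.llf - reduced.llf))
        assert np.isclose(p, stats.chi2.sf(chi2, 1))

    def test_identical_models_give_p_one(self, rng):
        full, _ = self._two_fits(rng)
        chi2, df, p = lr_test(full, full)
        assert chi2 == 0.0 and df == 0 and p == 1.0

    def test_chi2_384_is_p_005(self):
        # the df=1 5% critical value, via the same tail used by lr_test
        assert np.isclose(stats.chi2.sf(3.84, 1), 0.050, atol=5e-4)

    def test_non_nested_raises(self, rng):
        y, e, X = _sim_cox(rng, n=200)
        a = CoxFrailtyModel(y, e, X[:, :1], ["g"]).fit()
        b = CoxFrailtyModel(y, e, X[:, 1:], ["z"]).fit()
        with pytest.raises(ValueError):
            lr_test(a, b)

    def test_different_data_raises(self, rng):
        f1, _ = self._two_fits(rng)
        f2, _ = self._two_fits(rng)
        with pytest.raises(ValueError):
            lr_test(f1, f2)

    def test_aic_ladder_arithmetic(self):
        class Stub:
            def __init__(self, aic):
                self.aic = aic
                self.llf_integrated = -aic / 2
                self.df_aic = 0

            def _data_signature(self):
                return ("shared",)

        tab = aic_ladder([Stub(103), Stub(110), Stub(100)], ["b", "c", "a"])
        assert list(tab.model) == ["a", "b", "c"]
        assert np.allclose(tab.delta_aic, [0, 3, 10])
        assert list(tab.substantial) == [False, False, True]

    def test_ladder_order_invariant(self, rng):
        full, reduced = self._two_fits(rng)
        t1 = aic_ladder([full, reduced], ["f", "r"])
        t2 = aic_ladder([reduced, full], ["r", "f"])
        assert list(t1.model) == list(t2.model)


def _piecewise_nonph(rng, n):
    """Binary covariate whose effect switches on only late in the search:
    hazard 1 everywhere, except exp(1.5) for x=1 once y > 0.3."""
    x = rng.integers(0, 2, n)
    y = np.empty(n)
    for i in range(n):
        t = rng.exponential(1.0)
        if x[i] == 1 and t > 0.3:
            t = 0.3 + rng.exponential(np.exp(-1.5))
        y[i] = t
    return y, np.ones(n, int), x[:, None]


class TestPHDiagnostics:
    def test_residuals_sum_to_zero(self, rng):
        y, e, X = _sim_cox(rng, n=400)
        res = CoxFrailtyModel(y, e, X, ["g", "z"]).fit()
        _, resid = res.schoenfeld_residuals()
        assert np.allclose(resid.sum(axis=0), 0.0, atol=1e-6)

    def test_size_under_proportional_hazards(self):
        rejections = 0
        reps = 100
        for r in range(reps):
            rng = np.random.default_rng(5000 + r)
            y, e, X = _sim_cox(rng, n=300)
            res = CoxFrailtyModel(y, e, X, ["g", "z"]).fit()
            p = res.ph_test().p.iloc[0]
            rejections += p < 0.05
        assert rejections / reps < 0.12  # close to the nominal 5%

    def test_power_against_changing_effect(self):
        hits = 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(6000 + r)
            y, e, X = _piecewise_nonph(rng, 2000)
            res = CoxFrailtyModel(y, e, X, ["x"]).fit()
            hits += res.ph_test().p.iloc[0] < 0.05
        assert hits / reps > 0.8

    def test_too_few_events_raises(self):
        res = CoxFrailtyModel([1.0, 2.0, 3.0], [1, 0, 0], [[1.0], [0.0], [1.0]], ["x"]).fit()
        with pytest.raises(ValueError):
            res.ph_test()
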