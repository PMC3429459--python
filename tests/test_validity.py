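"""Dichotomization and multilevel logistic predictive-validity models."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import floatcatch as fc
from floatcatch.validity import (RandomInterceptLogit, attach_exposures,
                                 dichotomize_at_median, fit_multilevel_logistic)


class TestDichotomize:
    def test_half_split(self):
        x = np.arange(1, 11)
        d = dichotomize_at_median(x)
        assert d.sum() == 5 and d[:5].all()

    def test_tie_at_median_is_reference(self):
        d = dichotomize_at_median(np.array([1.0, 2.0, 3.0]))
        assert d.tolist() == [1, 0, 0]  # the median itself is reference

    def test_monotone_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 5, 101)
        np.testing.assert_array_equal(dichotomize_at_median(x),
                                      dichotomize_at_median(np.log(x)))

    def test_flipped_orientation(self):
        x = np.arange(1, 11)
        np.testing.assert_array_equal(
            dichotomize_at_median(x, high_is_exposure=True),
            1 - dichotomize_at_median(x) - (x == np.median(x)))

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            dichotomize_at_median(np.ones(5))


@pytest.fixture(scope="module")
def sim_cases():
    """Mid-sized simulated case table with known generating effects."""
    bg, _, _ = fc.generate_region(fc.RegionSpec(200, 10, seed=13))
    rng = np.random.default_rng(13)
    access = pd.Series(rng.uniform(0, 20, len(bg)), index=bg.index, name="SAU")
    dep = pd.Series(rng.normal(0, 1, len(bg)), index=bg.index)
    spec = fc.OutcomeModelSpec(intercept=-0.3, beta_access=np.log(1.5),
                               beta_deprivation=np.log(1.3),
                               random_intercept_sd=0.3, n_cases=6000, seed=17)
    cases = fc.generate_cases(bg, access, dep, spec)
    tagged = attach_exposures(cases, access.to_frame(), dep, measure="SAU")
    return bg, access, dep, tagged


class TestRandomInterceptLogit:
    def test_zero_variance_reduces_to_plain_logistic(self, sim_cases):
        _, _, _, tagged = sim_cases
        X = np.column_stack([np.ones(len(tagged)),
                             tagged["low_access"].to_numpy(float)])
        ours = RandomInterceptLogit(tagged["late_stage"], X,
                                    tagged["bg_id"]).fit(var_fixed=0.0)
        ref = sm.Logit(tagged["late_stage"].to_numpy(float), X).fit(disp=0)
        np.testing.assert_allclose(ours.params, ref.params, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_2x2_closed_form_odds_ratio(self):
        # (20,80;10,90): OR = (20*90)/(80*10) = 2.25
        y = np.repeat([1, 0, 1, 0], [20, 80, 10, 90])
        x = np.repeat([1, 1, 0, 0], [20, 80, 10, 90])
        groups = np.tile([0, 1], 100)
        X = np.column_stack([np.ones(200), x])
        res = RandomInterceptLogit(y, X, groups).fit(var_fixed=0.0)
        assert np.exp(res.params[1]) == pytest.approx(2.25, rel=1e-6)

    def test_estimates_random_intercept_variance(self):
        # strong clustering should produce a clearly positive variance
        rng = np.random.default_rng(1)
        n_groups, per = 150, 40
        u = rng.normal(0, 1.0, n_groups)
        g = np.repeat(np.arange(n_groups), per)
        x = rng.integers(0, 2, n_groups * per)
        eta = 0.3 * x + u[g]
        y = (rng.uniform(size=g.size) < 1 / (1 + np.exp(-eta))).astype(float)
        res = RandomInterceptLogit(y, np.column_stack([np.ones(g.size), x]), g).fit()
        assert 0.5 < res.sigma < 1.5
        assert res.params[1] == pytest.approx(0.3, abs=0.15)

    def test_scaled_deviance_is_minus_twice_loglik(self, sim_cases):
        _, _, _, tagged = sim_cases
        X = np.ones((len(tagged), 1))
        res = RandomInterceptLogit(tagged["late_stage"], X, tagged["bg_id"]).fit()
        assert res.scaled_deviance == pytest.approx(-2 * res.loglik)

    def test_complete_separation_raises(self):
        y = np.repeat([1, 0], [50, 50]).astype(float)
        x = y.copy()
        g = np.tile([0, 1], 50)
        with pytest.raises(fc.validity.ConvergenceError):
            RandomInterceptLogit(y, np.column_stack([np.ones(100), x]), g).fit(
                var_fixed=0.0)


class TestModelForms:
    def test_form_terms(self, sim_cases):
        _, _, _, tagged = sim_cases
        r1 = fit_multilevel_logistic(tagged, form="I")
        assert list(r1.terms.index) == ["intercept", "low_access",
                                        "age[50-64]", "age[65+]"]
        r2 = fit_multilevel_logistic(tagged, form="II")
        assert "race[African American]" in r2.terms.index
        r3 = fit_multilevel_logistic(tagged, form="III")
        assert "high_deprivation" in r3.terms.index

    def test_effects_recovered_in_form_iii(self, sim_cases):
        _, _, _, tagged = sim_cases
        res = fit_multilevel_logistic(tagged, form="III")
        t = res.terms
        assert t.loc["low_access", "ci_low"] < 1.5 < t.loc["low_access", "ci_high"]
        assert t.loc["low_access", "OR"] == pytest.approx(1.5, abs=0.25)

    def test_cis_contain_point(self, sim_cases):
        _, _, _, tagged = sim_cases
        res = fit_multilevel_logistic(tagged, form="II")
        t = res.terms
        assert ((t["ci_low"] <= t["OR"]) & (t["OR"] <= t["ci_high"])).all()
        assert (t["OR"] > 0).all()

    def test_joint_form_four_levels(self, sim_cases):
        _, _, _, tagged = sim_cases
        res = fit_multilevel_logistic(tagged, form="joint")
        for name in ("less_deprived:less_accessible",
                     "more_deprived:more_accessible",
                     "more_deprived:less_accessible"):
            assert name in res.terms.index

    def test_joint_matches_stratified_in_reference_stratum(self, sim_cases):
        # with exposures generated without interaction, the joint OR for
        # (less deprived, less accessible) tracks the stratified
        # less-deprived exposure OR
        _, _, _, tagged = sim_cases
        joint = fit_multilevel_logistic(tagged, form="joint", var_fixed=0.0)
        strat = fit_multilevel_logistic(tagged, form="stratified", var_fixed=0.0)
        a = joint.terms.loc["less_deprived:less_accessible", "log_or"]
        b = strat.strata["less_deprived"].terms.loc["low_access", "log_or"]
        assert a == pytest.approx(b, abs=0.05)

    def test_stratified_returns_both_strata(self, sim_cases):
        _, _, _, tagged = sim_cases
        res = fit_multilevel_logistic(tagged, form="stratified")
        assert set(res.strata) == {"less_deprived", "more_deprived"}

    def test_single_blockgroup_rejected(self, sim_cases):
        _, _, _, tagged = sim_cases
        sub = tagged[tagged["bg_id"] == tagged["bg_id"].iloc[0]]
        with pytest.raises(ValueError):
            fit_multilevel_logistic(sub, form="I")


class TestSuite:
    def test_full_battery_cardinality(self, sim_cases):
        bg, access, dep, _ = sim_cases
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {m: rng.uniform(0, 20, len(bg)) for m in fc.MEASURES}, index=bg.index)
        spec = fc.OutcomeModelSpec(n_cases=2000, seed=3)
        cases = fc.generate_cases(bg, table["SAU"], dep, spec)
        suite = fc.run_validity_suite(cases, table, dep, var_fixed=0.0)
        assert len(suite) == 9
        assert all(set(v) == set(fc.validity.FORMS) for v in suite.values())
        flat = fc.validity_table(suite)
        # 9 measures x (I, II, III, joint + 2 strata) model fits
        assert flat[["measure", "form"]].drop_duplicates().shape[0] == 9 * 6

    def test_travel_time_orientation_flipped(self, sim_cases):
        bg, access, dep, _ = sim_cases
        table = pd.concat([access.rename("SAU"), access.rename("DST")], axis=1)
        cases = fc.generate_cases(bg, access, dep,
                                  fc.OutcomeModelSpec(n_cases=500, seed=4))
        sau = attach_exposures(cases, table, dep, measure="SAU")
        dst = attach_exposures(cases, table, dep, measure="DST")
        # same raw values, opposite orientation: exposures are complementary
        both = sau["low_access"] + dst["low_access"]
        assert both.isin([0, 1]).all() and both.mean() > 0.9

    def test_deterministic(self, sim_cases):
        _, _, _, tagged = sim_cases
        a = fit_multilevel_logistic(tagged, form="I")
        b = fit_multilevel_logistic(tagged, form="I")
        pd.testing.assert_frame_equal(a.terms, b.terms)
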