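"""Service density and 2SFCA scores against hand and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import floatcatch as fc
from floatcatch.access import (DecaySpec, ZONAL_3_QUICK, ZONAL_3_SLOW,
                               ZONAL_6_QUICK, ZONAL_6_SLOW, decay_weight,
                               default_decay_specs, multi_year_average)

from conftest import random_od_instance


def brute_force_2sfca(times, machines, pops, spec, scale):
    """Literal triple-loop transcription of the two-step definition."""
    t = times.to_numpy()
    S = machines.to_numpy()
    P = pops.to_numpy()
    n, m = t.shape
    R = np.zeros(m)
    for j in range(m):
        denom = 0.0
        for k in range(n):
            if t[k, j] <= spec.t0:
                denom += decay_weight(t[k, j], spec) * P[k]
        R[j] = S[j] / denom if denom > 0 else 0.0
    A = np.zeros(n)
    for k in range(n):
        for j in range(m):
            if t[k, j] <= spec.t0:
                A[k] += decay_weight(t[k, j], spec) * R[j]
    return scale * A


class TestDecayWeight:
    @pytest.mark.parametrize("t,expected", [(7, 1.00), (12, 0.51), (28, 0.07),
                                            (31, 0.0)])
    def test_three_zone_quick(self, t, expected):
        spec = DecaySpec("zonal", zone_width=10, weights=ZONAL_3_QUICK)
        assert decay_weight(t, spec) == expected

    @pytest.mark.parametrize("t,expected", [(17, 0.70), (2, 1.00), (30, 0.37)])
    def test_six_zone_slow(self, t, expected):
        spec = DecaySpec("zonal", zone_width=5, weights=ZONAL_6_SLOW)
        assert decay_weight(t, spec) == expected

    def test_zone_boundaries_half_open(self):
        # band i covers ((i-1)w, iw]; an exact boundary stays in the lower band
        spec = DecaySpec("zonal", zone_width=10, weights=ZONAL_3_SLOW)
        assert decay_weight(10.0, spec) == 1.00
        assert decay_weight(10.0001, spec) == 0.75
        assert decay_weight(0.0, spec) == 1.00

    def test_continuous_endpoints(self):
        spec = DecaySpec("continuous", beta=15.0)
        assert decay_weight(0.0, spec) == pytest.approx(1.0)
        assert decay_weight(30.0, spec) == pytest.approx(0.0, abs=1e-15)
        assert decay_weight(30.5, spec) == 0.0

    def test_continuous_monotone_decreasing(self):
        spec = DecaySpec("continuous", beta=10.0)
        ts = np.linspace(0, 30, 100)
        w = decay_weight(ts, spec)
        assert np.all(np.diff(w) < 0)

    def test_unweighted_is_indicator(self):
        spec = DecaySpec("none")
        assert decay_weight(29.9, spec) == 1.0
        assert decay_weight(30.0, spec) == 1.0
        assert decay_weight(30.1, spec) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            decay_weight(-1.0, DecaySpec("none"))

    def test_quick_weights_below_slow(self):
        # quicker decay never exceeds slower decay beyond the first band
        for t in np.linspace(10.01, 30, 50):
            q3 = decay_weight(t, DecaySpec("zonal", zone_width=10, weights=ZONAL_3_QUICK))
            s3 = decay_weight(t, DecaySpec("zonal", zone_width=10, weights=ZONAL_3_SLOW))
            assert q3 <= s3
        for t in np.linspace(5.01, 30, 50):
            q6 = decay_weight(t, DecaySpec("zonal", zone_width=5, weights=ZONAL_6_QUICK))
            s6 = decay_weight(t, DecaySpec("zonal", zone_width=5, weights=ZONAL_6_SLOW))
            assert q6 <= s6

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DecaySpec("zonal", zone_width=10, weights=(1.0, 0.5))  # does not span t0
        with pytest.raises(ValueError):
            DecaySpec("zonal", zone_width=10, weights=(0.9, 0.5, 0.1))  # first != 1
        with pytest.raises(ValueError):
            DecaySpec("zonal", zone_width=10, weights=(1.0, 0.5, 0.6))  # increasing
        with pytest.raises(ValueError):
            DecaySpec("continuous", beta=-3.0)
        with pytest.raises(ValueError):
            DecaySpec("gaussian")


class TestServiceDensity:
    def test_toy_values(self, toy_times, toy_supply, toy_population):
        des = fc.service_density(toy_times, toy_supply, toy_population)
        # b1/b2 reach both machines, b3 only the 5-minute one
        assert des.tolist() == [200.0, 200.0, 100.0]

    def test_no_facility_in_reach_gives_zero(self, toy_supply):
        times = pd.DataFrame([[40.0, 50.0]], index=["b1"], columns=["f1", "f2"])
        pops = pd.Series([100.0], index=["b1"])
        assert fc.service_density(times, toy_supply, pops).iloc[0] == 0.0

    def test_zero_population_rejected(self, toy_times, toy_supply):
        pops = pd.Series([100.0, 0.0, 100.0], index=["b1", "b2", "b3"])
        with pytest.raises(ValueError, match="b2"):
            fc.service_density(toy_times, toy_supply, pops)


class TestTwoStepFCA:
    def test_toy_hand_values(self, toy_times, toy_supply, toy_population):
        a = fc.two_step_fca(toy_times, toy_supply, toy_population, DecaySpec("none"))
        # R1 = 1/200, R2 = 1/300; A1 = A2 = R1 + R2, A3 = R2 (x 10^4)
        assert a.loc["b1"] == pytest.approx(1e4 / 120)
        assert a.loc["b2"] == pytest.approx(1e4 / 120)
        assert a.loc["b3"] == pytest.approx(1e4 / 300)

    def test_conservation_identity(self, toy_times, toy_supply, toy_population):
        a = fc.two_step_fca(toy_times, toy_supply, toy_population,
                            DecaySpec("none"), scale=1.0)
        assert (toy_population * a).sum() == pytest.approx(2.0, abs=1e-12)

    def test_conservation_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            times, machines, pops = random_od_instance(rng)
            a = fc.two_step_fca(times, machines, pops, DecaySpec("none"), scale=1.0)
            reachable = (times.to_numpy() <= 30.0).any(axis=0)
            expected = machines.to_numpy()[reachable].sum()
            assert (pops * a).sum() == pytest.approx(expected, abs=1e-9)

    def test_single_pair_reduces_to_density(self):
        times = pd.DataFrame([[12.0]], index=["b1"], columns=["f1"])
        machines = pd.Series([3.0], index=["f1"])
        pops = pd.Series([250.0], index=["b1"])
        a = fc.two_step_fca(times, machines, pops, DecaySpec("none"))
        d = fc.service_density(times, machines, pops)
        assert a.iloc[0] == pytest.approx(d.iloc[0]) == pytest.approx(1e4 * 3 / 250)

    def test_all_ones_zonal_equals_unweighted(self):
        rng = np.random.default_rng(3)
        times, machines, pops = random_od_instance(rng, n_bg=15, n_fac=4)
        flat = DecaySpec("zonal", zone_width=10, weights=(1.0, 1.0, 1.0))
        sau = fc.two_step_fca(times, machines, pops, DecaySpec("none"))
        saz = fc.two_step_fca(times, machines, pops, flat)
        pd.testing.assert_series_equal(sau, saz)

    @pytest.mark.parametrize("spec_name", ["SAU", "SAC", "SA3Q", "SA3S", "SA6Q", "SA6S"])
    def test_matches_triple_loop_oracle(self, spec_name):
        rng = np.random.default_rng(11)
        spec = default_decay_specs()[spec_name]
        for _ in range(10):
            times, machines, pops = random_od_instance(rng)
            fast = fc.two_step_fca(times, machines, pops, spec)
            slow = brute_force_2sfca(times, machines, pops, spec, 1e4)
            np.testing.assert_allclose(fast.to_numpy(), slow, rtol=1e-12, atol=0)

    def test_monotone_in_supply(self):
        rng = np.random.default_rng(5)
        times, machines, pops = random_od_instance(rng, n_bg=12, n_fac=4)
        spec = default_decay_specs()["SA3Q"]
        base = fc.two_step_fca(times, machines, pops, spec)
        bumped = machines.copy()
        bumped.iloc[0] += 1
        after = fc.two_step_fca(times, bumped, pops, spec)
        shares = (times.iloc[:, 0] <= spec.t0).to_numpy()
        assert np.all(after.to_numpy()[shares] >= base.to_numpy()[shares])
        np.testing.assert_allclose(after.to_numpy()[~shares], base.to_numpy()[~shares])

    def test_empty_catchment_contributes_nothing(self, toy_supply):
        times = pd.DataFrame([[5.0, 90.0]], index=["b1"], columns=["f1", "f2"])
        pops = pd.Series([100.0], index=["b1"])
        a = fc.two_step_fca(times, toy_supply, pops, DecaySpec("none"), scale=1.0)
        assert a.iloc[0] == pytest.approx(1 / 100)


class TestMultiYearAverage:
    def test_idempotent_on_identical_years(self, region200):
        acc = region200["access"]
        avg = multi_year_average([acc, acc, acc])
        pd.testing.assert_frame_equal(avg, acc)

    def test_cellwise_mean(self):
        a = pd.DataFrame({"DES": [10.0]}, index=["b1"])
        b = pd.DataFrame({"DES": [20.0]}, index=["b1"])
        assert multi_year_average([a, b]).loc["b1", "DES"] == 15.0

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(8)
        years = [pd.DataFrame(rng.uniform(0, 20, (6, 3)),
                              index=list("abcdef"), columns=["DES", "SAU", "SAC"])
                 for _ in range(5)]
        avg = multi_year_average(years)
        oracle = sum(y.to_numpy() for y in years) / 5
        np.testing.assert_allclose(avg.to_numpy(), oracle)

    def test_misaligned_rejected(self):
        a = pd.DataFrame({"DES": [1.0]}, index=["b1"])
        b = pd.DataFrame({"DES": [1.0]}, index=["b2"])
        with pytest.raises(ValueError):
            multi_year_average([a, b])


class TestComputeAllMeasures:
    def test_column_set_and_composition(self, toy_times, toy_supply, toy_population):
        table = fc.compute_all_measures(toy_times, toy_supply, toy_population)
        assert list(table.columns) == list(fc.MEASURES)
        sau = fc.two_step_fca(toy_times, toy_supply, toy_population, DecaySpec("none"))
        pd.testing.assert_series_equal(table["SAU"], sau, check_names=False)
        assert table["DST"].tolist() == [5.0, 15.0, 5.0]

    def test_multi_year_machines_average(self, toy_times, toy_population):
        machines = pd.DataFrame({"y1": [1.0, 1.0], "y2": [3.0, 1.0]},
                                index=["f1", "f2"])
        table = fc.compute_all_measures(toy_times, machines, toy_population)
        y1 = fc.compute_all_measures(toy_times, machines["y1"], toy_population)
        y2 = fc.compute_all_measures(toy_times, machines["y2"], toy_population)
        for col in ("DES", "SAU", "SA6S"):
            np.testing.assert_allclose(table[col], (y1[col] + y2[col]) / 2)

    def test_dst_le_dst5_everywhere(self, region200):
        acc = region200["access"]
        assert (acc["DST"] <= acc["DST5"] + 1e-12).all()

    def test_scores_nonnegative(self, region200):
        assert (region200["access"].to_numpy() >= 0).all()
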