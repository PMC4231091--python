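"""The intensity-ratio and Solomon-Bloembergen conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from premap import (BoundKind, DistanceWindow, PREParameters, PRERecord,
                    RatioFlag, RatioRecord, distance_from_gamma2,
                    distance_from_rate, forward_ratio, gamma2_from_distance,
                    gamma2_from_ratio, invert_ratio, load_parameters,
                    quantifiable_window, r2_from_linewidth, tauc_sensitivity)


class TestR2FromLinewidth:
    def test_pi_times_width(self):
        assert r2_from_linewidth(10.0) == pytest.approx(math.pi * 10.0)

    def test_derived_value(self):
        # 15.9155 Hz is 50/pi: the linewidth of a 50 s^-1 resonance
        assert r2_from_linewidth(15.9155) == pytest.approx(50.0, rel=1e-4)

    @pytest.mark.parametrize("bad", [0.0, -3.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            r2_from_linewidth(bad)


class TestForwardRatio:
    def test_zero_rate_gives_unity(self, params):
        for r2 in (20.0, 40.0, 80.0):
            assert forward_ratio(0.0, r2, params) == pytest.approx(1.0)

    def test_monotone_decreasing_limit_zero(self, params):
        grid = np.linspace(0.0, 2000.0, 200)
        vals = [forward_ratio(g, 40.0, params) for g in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert forward_ratio(1e6, 40.0, params) < 1e-12

    def test_direct_evaluation(self, params):
        # ratio = R2 * exp(-Gamma2*t) / (R2 + Gamma2), independent oracle
        expected = 40.0 * math.exp(-23.0 * 0.010) / (40.0 + 23.0)
        assert forward_ratio(23.0, 40.0, params) == pytest.approx(expected)

    def test_negative_rate_rejected(self, params):
        with pytest.raises(ValueError):
            forward_ratio(-1.0, 40.0, params)


class TestRatioInversion:
    @pytest.mark.parametrize("r2", [20.0, 40.0, 80.0])
    def test_roundtrip_identity(self, params, r2):
        for gamma in np.geomspace(0.1, 500.0, 34):
            ratio = forward_ratio(gamma, r2, params)
            assert invert_ratio(ratio, r2, params) == pytest.approx(
                gamma, rel=1e-6)

    def test_ratio_of_one_maps_to_zero(self, params):
        rec = RatioRecord(7, 1.0, 0.05)
        out = gamma2_from_ratio(rec, 40.0, params)
        assert out.gamma2 == 0.0
        assert out.bound is BoundKind.measured

    def test_half_ratio_matches_grid_scan(self, params):
        # independent oracle: dense grid scan of the forward model
        grid = np.linspace(0.0, 500.0, 2_000_001)
        vals = 40.0 * np.exp(-grid * params.t_evolution) / (40.0 + grid)
        oracle = grid[np.argmin(np.abs(vals - 0.5))]
        rec = RatioRecord(1, 0.5, 0.025)
        out = gamma2_from_ratio(rec, 40.0, params)
        assert out.gamma2 == pytest.approx(oracle, abs=5e-4)

    def test_undetected_becomes_lower_bound(self, params):
        rec = RatioRecord(3, 0.05, 0.0, RatioFlag.undetected_para)
        out = gamma2_from_ratio(rec, 40.0, params)
        assert out.bound is BoundKind.lower_bound
        assert out.gamma2 == pytest.approx(
            invert_ratio(0.05, 40.0, params))
        assert out.gamma2_hi == math.inf

    def test_missing_dia_rejected(self, params):
        rec = RatioRecord(3, float("nan"), float("nan"),
                          RatioFlag.missing_dia)
        with pytest.raises(ValueError, match="diamagnetic"):
            gamma2_from_ratio(rec, 40.0, params)

    def test_error_band_ordered(self, params):
        rec = RatioRecord(2, 0.4, 0.02)
        out = gamma2_from_ratio(rec, 40.0, params)
        assert out.gamma2_lo < out.gamma2 < out.gamma2_hi


class TestSolomonBloembergen:
    def test_reference_value_at_20A(self, params):
        # direct evaluation: K/r^6 * (4 tau_c + 3 tau_c/(1+(w tau_c)^2))
        assert gamma2_from_distance(20.0, params) == pytest.approx(
            12.3, abs=0.05)

    def test_inverse_sixth_power_scaling(self, params):
        assert gamma2_from_distance(10.0, params) == pytest.approx(
            64.0 * gamma2_from_distance(20.0, params))

    def test_vanishes_at_infinity(self, params):
        assert gamma2_from_distance(1e6, params) < 1e-20

    @pytest.mark.parametrize("r", [5.0, 12.0, 18.0, 25.0, 40.0])
    def test_analytic_roundtrip(self, params, r):
        gamma = gamma2_from_distance(r, params)
        assert distance_from_rate(gamma, params) == pytest.approx(
            r, rel=1e-9)

    def test_halving_rate_scales_distance(self, params):
        gamma = gamma2_from_distance(18.0, params)
        r_half = distance_from_rate(gamma / 2.0, params)
        assert r_half == pytest.approx(18.0 * 2.0 ** (1.0 / 6.0), rel=1e-9)


class TestDistanceFromGamma2:
    def test_windows(self, params):
        cases = {
            8.0: DistanceWindow.below_floor,
            18.0: DistanceWindow.quantifiable,
            30.0: DistanceWindow.above_ceiling,
        }
        for r_true, window in cases.items():
            gamma = gamma2_from_distance(r_true, params)
            rec = PRERecord(1, gamma, gamma * 0.9, gamma * 1.1)
            est = distance_from_gamma2(rec, params)
            assert est.window is window
            assert est.r == pytest.approx(r_true, rel=1e-9)

    def test_zero_rate_is_ceiling_sentinel(self, params):
        rec = PRERecord(1, 0.0, 0.0, 1.0)
        est = distance_from_gamma2(rec, params)
        assert est.window is DistanceWindow.above_ceiling
        assert math.isinf(est.r)
        assert math.isinf(est.r_hi)

    def test_lower_bound_rate_is_floor_upper_limit(self, params):
        gamma = gamma2_from_distance(10.0, params)
        rec = PRERecord(1, gamma, gamma, math.inf,
                        bound=BoundKind.lower_bound)
        est = distance_from_gamma2(rec, params)
        assert est.window is DistanceWindow.below_floor
        assert est.r_lo == 0.0  # infinite rate bound -> distance 0
        assert est.r == pytest.approx(10.0, rel=1e-9)

    def test_error_bars_ordered(self, params):
        gamma = gamma2_from_distance(16.0, params)
        rec = PRERecord(1, gamma, gamma * 0.8, gamma * 1.25)
        est = distance_from_gamma2(rec, params)
        assert est.r_lo <= est.r <= est.r_hi


class TestTaucSensitivity:
    def test_zero_delta_is_zero(self, params):
        assert tauc_sensitivity([10.0, 20.0], params, 0.0) == 0.0

    def test_paper_bound_two_ns(self, params):
        grid = np.linspace(5.0, 40.0, 36)
        assert tauc_sensitivity(grid, params, 2e-9) < 0.06

    def test_matches_large_field_limit(self, params):
        # with the dispersive term negligible, the change is
        # (1 +/- delta/tau_c)^(1/6) - 1
        delta = 2e-9
        limit = max(abs((1 + delta / params.tau_c) ** (1 / 6) - 1),
                    abs((1 - delta / params.tau_c) ** (1 / 6) - 1))
        got = tauc_sensitivity([20.0], params, delta)
        assert got == pytest.approx(limit, rel=1e-3)

    def test_delta_must_be_smaller_than_tauc(self, params):
        with pytest.raises(ValueError):
            tauc_sensitivity([20.0], params, params.tau_c)


class TestQuantifiableWindow:
    def test_ordered_and_finite(self, params):
        for r2 in (30.0, 45.0, 60.0):
            r_min, r_max = quantifiable_window(r2, params, 0.05)
            assert 0 < r_min < r_max < math.inf

    def test_zero_sigma_gives_infinite_ceiling(self, params):
        r_min, r_max = quantifiable_window(40.0, params, 0.0)
        assert math.isinf(r_max)
        assert r_min > 0

    def test_edges_solve_the_stated_ratios(self, params):
        r_min, r_max = quantifiable_window(50.0, params, 0.05)
        g_min = gamma2_from_distance(r_min, params)
        g_max = gamma2_from_distance(r_max, params)
        assert forward_ratio(g_min, 50.0, params) == pytest.approx(
            params.floor_ratio, rel=1e-6)
        assert forward_ratio(g_max, 50.0, params) == pytest.approx(
            0.95, rel=1e-6)


@settings(deadline=None, max_examples=60)
@given(gamma=st.floats(0.1, 500.0), r2=st.sampled_from([20.0, 40.0, 80.0]))
def test_inversion_property(gamma, r2):
    params = PREParameters()
    ratio = forward_ratio(gamma, r2, params)
    assert invert_ratio(ratio, r2, params) == pytest.approx(gamma, rel=1e-6)


class TestLoadParameters:
    def test_config_spellings(self):
        p = load_parameters({"t_evolution_ms": 10, "tau_c_ns": 16,
                             "spectrometer_mhz": 600, "K": 1.23e-32,
                             "r_window": [12, 25]})
        assert p.t_evolution == pytest.approx(0.010)
        assert p.tau_c == pytest.approx(1.6e-8)
        assert p.k_label == pytest.approx(1.23e-32)
        assert p.r_window == (12.0, 25.0)

    def test_unknown_key_rejected(self):
        with pytest.raises(KeyError):
            load_parameters({"tau_sea_ns": 16})

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            PREParameters(tau_c=-1e-9)
        with pytest.raises(ValueError):
            PREParameters(r_window=(25.0, 12.0))
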