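"""SNR, NEP, DOR, and drift metrics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirtwin import qc
from nirtwin.qc import (NEPParams, PhysicalConstants, TwoStateMeasurement,
                        allan_deviation, dynamic_optical_range,
                        linear_drift_rate, nep_actual, nep_theoretical,
                        run_snr_protocol, sigma3_occupancy, snr_two_state)


def two_state(diffs, base=500.0):
    d = np.asarray(diffs, float)
    return TwoStateMeasurement(mgv_a=base + d, mgv_b=np.full(d.size, base))


class TestSNR:
    def test_hand_computed_example(self):
        # mean 10, sample sd 0.16330 -> 20 log10(61.24) = 35.74 dB
        m = two_state([10.0, 10.2, 9.8, 10.0])
        assert snr_two_state(m) == pytest.approx(35.74, abs=0.01)

    def test_zero_variance_sentinel(self):
        assert snr_two_state(two_state([5.0, 5.0, 5.0, 5.0])) == math.inf

    def test_swapped_states_error(self):
        with pytest.raises(ValueError, match="swapped"):
            snr_two_state(two_state([-10.0, -10.2, -9.8, -10.0]))

    def test_minimum_repeats_enforced(self):
        with pytest.raises(ValueError, match="repeats"):
            TwoStateMeasurement(mgv_a=np.array([1.0]), mgv_b=np.array([0.0]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(offset=st.floats(min_value=-1e4, max_value=1e4))
    def test_invariant_to_common_offset(self, offset):
        d = np.array([10.0, 10.2, 9.8, 10.1])
        base = snr_two_state(TwoStateMeasurement(500.0 + d, np.full(4, 500.0)))
        shifted = snr_two_state(TwoStateMeasurement(500.0 + offset + d,
                                                    np.full(4, 500.0 + offset)))
        assert shifted == pytest.approx(base, rel=1e-9)


class TestNEP:
    P695 = NEPParams(wavelength_nm=695.0, eta=0.8406)
    P830 = NEPParams(wavelength_nm=830.0, eta=0.5333)

    def test_theoretical_matches_one_line_oracle(self):
        pix, total = nep_theoretical(self.P695)
        oracle = (3.57 * 6.62607015e-34 * 299792458.0
                  / (695e-9 * 0.025 * 0.8406 * math.sqrt(0.09)))
        assert pix == pytest.approx(oracle, rel=1e-12)
        assert total == pytest.approx(math.sqrt(32686) * oracle, rel=1e-12)

    def test_zero_read_noise_zero_nep(self):
        p = NEPParams(wavelength_nm=695.0, eta=0.8406, read_noise_e=0.0)
        assert nep_theoretical(p) == (0.0, 0.0)

    def test_wavelength_ratio_matches_published_ratio(self):
        # 830/695 NEP ratio = (695 * eta695) / (830 * eta830) ~ 1.320,
        # against the published 6.96 / 5.29 = 1.3157 (within 0.5%)
        _, n695 = nep_theoretical(self.P695)
        _, n830 = nep_theoretical(self.P830)
        assert n830 / n695 == pytest.approx(6.96 / 5.29, rel=0.005)

    def test_actual_zero_mgv(self):
        assert nep_actual(0.0, self.P695) == 0.0

    def test_actual_matches_one_line_oracle(self):
        got = nep_actual(2.0, self.P695)
        q = 32686 * 2.0 * 2.33
        oracle = (q * 6.62607015e-34 * 299792458.0
                  / (695e-9 * 0.025 * 0.8406 * math.sqrt(0.09)))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_actual_linear_in_mgv(self):
        assert nep_actual(4.0, self.P695) == pytest.approx(
            2 * nep_actual(2.0, self.P695), rel=1e-12)


class TestDOR:
    @pytest.mark.parametrize("mx,mn,expected", [
        (4095.0, 1.87, 33.40),
        (4095.0, 1.92, 33.29),
    ])
    def test_published_values(self, mx, mn, expected):
        assert dynamic_optical_range(mx, mn) == pytest.approx(expected, abs=0.005)

    def test_equal_bounds_zero(self):
        assert dynamic_optical_range(100.0, 100.0) == 0.0

    def test_monotonicity(self):
        base = dynamic_optical_range(4095.0, 2.0)
        assert dynamic_optical_range(5000.0, 2.0) > base
        assert dynamic_optical_range(4095.0, 1.0) > base

    def test_non_positive_min_rejected(self):
        with pytest.raises(ValueError):
            dynamic_optical_range(4095.0, 0.0)


class TestDrift:
    def test_exact_ramp(self):
        t_h = np.arange(18000) / 5.0 / 3600.0
        series = 1.0 + 0.01 * (t_h - t_h.mean())
        assert linear_drift_rate(series, 5.0) == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_zero_rate(self):
        assert linear_drift_rate(np.full(6000, 3.0), 5.0) == pytest.approx(0.0, abs=1e-12)

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="10 minutes"):
            linear_drift_rate(np.ones(100), 5.0)

    def test_allan_constant_zero(self):
        dev = allan_deviation(np.full(5000, 2.0), 5.0, [0.2, 1.0, 10.0])
        assert all(v == 0.0 for v in dev.values())

    def test_allan_alternating_two_sample_form(self):
        # +a/-a alternation at tau = one sample: sigma_y = a sqrt(2)
        a = 0.7
        series = a * np.resize([1.0, -1.0], 4000)
        dev = allan_deviation(series, 5.0, [0.2], normalize="none")
        assert dev[0.2] == pytest.approx(a * math.sqrt(2), rel=1e-6)

    def test_allan_empty_tau_grid_rejected(self):
        with pytest.raises(ValueError, match="tau grid"):
            allan_deviation(np.ones(100), 5.0, [1000.0])

    def test_allan_triangle_property(self, rng):
        # compare in raw units where the triangle inequality is exact
        x = rng.normal(0, 1, 4000)
        y = rng.normal(0, 2, 4000)
        taus = [0.2, 1.0, 5.0, 20.0]
        dx = allan_deviation(x, 5.0, taus, normalize="none")
        dy = allan_deviation(y, 5.0, taus, normalize="none")
        dxy = allan_deviation(x + y, 5.0, taus, normalize="none")
        for tau in taus:
            assert dxy[tau] <= dx[tau] + dy[tau] + 1e-12


class TestSigma3:
    def test_constant_series(self):
        assert sigma3_occupancy(np.full(100, 5.0)) == 100.0

    def test_gaussian_occupancy(self, rng):
        x = rng.normal(0, 1, 300_000)
        assert sigma3_occupancy(x) == pytest.approx(99.73, abs=0.08)

    def test_outlier_construction(self, rng):
        x = rng.normal(0, 1, 20_000)
        n_out = 200  # 1% of samples thrown far outside
        x[:n_out] = 50.0
        occ = sigma3_occupancy(x)
        assert occ == pytest.approx(99.0, abs=0.2)


class TestSNRProtocol:
    def test_noiseless_sentinel_on_all_channels(self, noiseless_rig):
        snrs = run_snr_protocol(noiseless_rig.schedule, noiseless_rig.cmap,
                                noiseless_rig.layout, noiseless_rig.sensor,
                                seed=1, repeats=4)
        assert len(snrs) == 2 * len(noiseless_rig.cmap)
        assert all(v == math.inf for v in snrs.values())

    def test_shot_noise_power_scaling(self, small_rig):
        # in the shot-noise-limited regime, halving the operating power
        # lowers the two-state SNR by 10 log10(2) ~ 3 dB (the signal halves while
        # the noise falls by sqrt(2))
        full = run_snr_protocol(small_rig.schedule, small_rig.cmap,
                                small_rig.layout, small_rig.sensor, seed=2,
                                state_a_mgv=800.0, repeats=30)
        half = run_snr_protocol(small_rig.schedule, small_rig.cmap,
                                small_rig.layout, small_rig.sensor, seed=3,
                                state_a_mgv=400.0, repeats=30)
        drops = [full[k] - half[k] for k in full]
        assert np.mean(drops) == pytest.approx(10 * math.log10(2), abs=1.0)
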