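"""Forward optics, phantom recipes, and the experiment generators."""

import math

import numpy as np
import pytest

from nirtwin import phantoms as ph
from nirtwin import pipeline as pl
from nirtwin import qc


class TestDiffusionReflectance:
    def test_mueff_closed_form(self):
        assert ph.mueff(0.01, 2.3) == pytest.approx(math.sqrt(3 * 0.01 * 2.31),
                                                    rel=1e-12)
        assert ph.mueff(0.01, 2.3) == pytest.approx(0.2632, abs=5e-5)

    def test_monotone_decreasing_in_mua_and_rho(self):
        r1 = ph.kienle_reflectance(0.01, 2.3, 30.0)
        r2 = ph.kienle_reflectance(0.02, 2.3, 30.0)
        assert r2 < r1
        mua = np.linspace(0.005, 0.05, 40)
        refl = ph.kienle_reflectance(mua, 2.3, 30.0)
        assert np.all(np.diff(refl) < 0)
        assert ph.kienle_reflectance(0.01, 2.3, 35.0) < r1

    def test_against_independent_reimplementation(self):
        # same closed form coded from scratch
        def oracle(mua, musp, rho, n=1.33):
            mut = mua + musp
            D = 1 / (3 * mut)
            ueff = math.sqrt(3 * mua * mut)
            z0 = 1 / mut
            rd = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
            zb = 2 * (1 + rd) / (1 - rd) * D
            r1 = math.hypot(rho, z0)
            r2 = math.hypot(rho, z0 + 2 * zb)
            return (z0 * (ueff + 1 / r1) * math.exp(-ueff * r1) / r1**2
                    + (z0 + 2 * zb) * (ueff + 1 / r2) * math.exp(-ueff * r2) / r2**2
                    ) / (4 * math.pi)

        for mua in (0.00899, 0.011, 0.034, 0.046):
            got = float(ph.kienle_reflectance(mua, 2.3, 30.0))
            assert got == pytest.approx(oracle(mua, 2.3, 30.0), rel=1e-10)

    def test_non_diffusive_medium_is_hard_error(self):
        with pytest.raises(ValueError, match="non-diffusive"):
            ph.kienle_reflectance(2.5, 2.3, 30.0)
        with pytest.raises(ValueError, match="non-diffusive"):
            ph.OpticalMedium(mua={695.0: 2.5}, musp={695.0: 2.3})

    def test_medium_interface_and_marginal_warning(self):
        m = ph.OpticalMedium(mua={695.0: 0.01, 830.0: 0.012},
                             musp={695.0: 2.3, 830.0: 1.9})
        out = ph.diffusion_reflectance(m, 30.0)
        assert set(out) == {695.0, 830.0} and all(v > 0 for v in out.values())
        with pytest.warns(UserWarning, match="marginal"):
            ph.OpticalMedium(mua={695.0: 0.3}, musp={695.0: 2.3})

    def test_dpf_positive_and_decreasing_with_absorption(self):
        d1 = ph.diffusion_dpf(0.008, 2.3, 30.0)
        d2 = ph.diffusion_dpf(0.05, 2.3, 30.0)
        assert d1 > d2 > 0


class TestIntralipid:
    def test_zero_concentration(self):
        assert ph.intralipid_musp(0.0, 695.0) == 0.0

    def test_inverse_round_trip(self):
        c = ph.intralipid_fraction_for_musp(2.3, 695.0)
        assert ph.intralipid_musp(c, 695.0) == pytest.approx(2.3, rel=1e-12)
        assert 0.01 < c < 0.05  # a few percent lipid is the realistic regime

    def test_forward_matches_inline_empirical_formula(self):
        lam = 0.695
        mus_full = 16.0 * lam ** -2.4
        g = 1.1 - 0.58 * lam
        oracle = (0.01 / 0.10) * mus_full * (1 - g)
        assert ph.intralipid_musp(0.01, 695.0) == pytest.approx(oracle, rel=1e-12)

    def test_wavelength_validity_window(self):
        with pytest.raises(ValueError):
            ph.intralipid_musp(0.01, 1200.0)


class TestTitration:
    def test_zero_steps_returns_base_only(self):
        t = ph.InkTitration(base_mua=0.009, ink_specific_absorption=1e-4, n_steps=0)
        assert ph.titration_mua_series(t).tolist() == [0.009]

    @pytest.mark.parametrize("preset,lo,hi", [
        (ph.baseline_titration, 0.00899, 0.01100),
        (ph.low_absorption_titration, 0.01192, 0.01254),
        (ph.high_absorption_titration, 0.03366, 0.04639),
    ])
    def test_preset_endpoints(self, preset, lo, hi):
        series = ph.titration_mua_series(preset(9))
        assert series[0] == pytest.approx(lo, rel=1e-12)
        assert series[-1] == pytest.approx(hi, rel=1e-12)
        assert np.all(np.diff(series) > 0)

    def test_series_strictly_increasing_required(self):
        with pytest.raises(ValueError):
            ph.InkTitration(base_mua=0.009, ink_specific_absorption=0.0, n_steps=3)

    def test_translation_to_830nm(self):
        series = ph.titration_mua_series(ph.baseline_titration(4))
        at830 = ph.titration_mua_at(series, 830.0)
        # water background swapped, ink part scaled
        expected0 = ph.WATER_MUA_MM[830.0] + (series[0] - ph.WATER_MUA_MM[695.0]) * 0.85
        assert at830[0] == pytest.approx(expected0, rel=1e-12)
        assert np.all(np.diff(at830) > 0)


class TestBloodPhantom:
    def test_zero_thb_gives_background(self):
        p = ph.BloodPhantom(total_hemoglobin_mM=0.0)
        assert ph.blood_mua(p, 0.5, 830.0) == pytest.approx(
            p.background_mua[830.0], rel=1e-12)

    def test_oxy_exceeds_deoxy_absorption_at_830(self):
        p = ph.BloodPhantom()
        eo, er = p.eps(830.0)
        assert eo > er  # table property driving the sign below
        assert ph.blood_mua(p, 1.0, 830.0) > ph.blood_mua(p, 0.0, 830.0)

    def test_deoxy_exceeds_oxy_absorption_at_695(self):
        p = ph.BloodPhantom()
        assert ph.blood_mua(p, 0.0, 695.0) > ph.blood_mua(p, 1.0, 695.0)

    def test_affine_in_so2(self):
        p = ph.BloodPhantom()
        lo, mid, hi = (ph.blood_mua(p, s, 695.0) for s in (0.0, 0.5, 1.0))
        assert mid == pytest.approx((lo + hi) / 2, rel=1e-12)

    def test_so2_domain_enforced(self):
        with pytest.raises(ValueError):
            ph.blood_mua(ph.BloodPhantom(), 1.2, 695.0)


class TestDeoxygenationCourse:
    def test_zero_depletion_constant(self):
        c = ph.deoxygenation_course(300.0, 5, so2_end=1.0)
        assert np.allclose(c.so2, 1.0)

    def test_default_course_contract(self):
        c = ph.deoxygenation_course(600.0, 12)
        assert c.so2[0] == pytest.approx(1.0, abs=1e-12)
        assert c.so2[-1] <= 0.01
        assert np.all(np.diff(c.so2) <= 1e-12)  # monotone non-increasing

    def test_reference_samples_read_the_course(self):
        c = ph.deoxygenation_course(600.0, 10)
        assert c.reference_times_s.size == 10
        looked_up = np.interp(c.reference_times_s, c.times_s, c.so2)
        assert np.allclose(c.reference_so2, looked_up)


class TestVFT:
    def test_sample_count(self):
        v = ph.vft_hemodynamics(ph.VFTDesign(), 5.0, seed=1)
        assert v.times_s.size == 150 * 5
        assert v.hbo_true_mM.size == v.times_s.size

    def test_zero_amplitude_zero_noise_flat(self):
        d = ph.VFTDesign(hbo_peak_mM=0.0, hbr_peak_mM=0.0, cardiac_amp_mM=0.0,
                         respiratory_amp_mM=0.0, mayer_amp_mM=0.0,
                         motion_events=())
        v = ph.vft_hemodynamics(d, 5.0, seed=1)
        for mat in v.intensities.values():
            assert np.allclose(mat, 1.0)

    def test_forward_then_invert_recovers_truth(self):
        d = ph.VFTDesign(cardiac_amp_mM=0.0, respiratory_amp_mM=0.0,
                         mayer_amp_mM=0.0, motion_events=())
        v = ph.vft_hemodynamics(d, 5.0, seed=2)
        table = pl.ExtinctionTable(
            eps={wl: ph.extinction_mm_mM(wl) for wl in (695.0, 830.0)},
            dpf=dict(v.dpf), pathlength_mm=v.pathlength_mm)
        dod = {wl: -np.log10(v.intensities[wl][0]) for wl in (695.0, 830.0)}
        hbo, hbr = pl.mbll_invert(dod, table)
        assert np.max(np.abs(hbo - v.hbo_true_mM)) < 1e-9
        assert np.max(np.abs(hbr - v.hbr_true_mM)) < 1e-9

    def test_hbr_opposite_signed(self):
        v = ph.vft_hemodynamics(ph.VFTDesign(), 5.0, seed=3)
        i = np.argmax(v.hbo_true_mM)
        assert v.hbo_true_mM[i] > 0 > v.hbr_true_mM[i]

    def test_reproducible_under_seed(self):
        a = ph.vft_hemodynamics(ph.VFTDesign(), 5.0, seed=11)
        b = ph.vft_hemodynamics(ph.VFTDesign(), 5.0, seed=11)
        for wl in a.intensities:
            assert np.array_equal(a.intensities[wl], b.intensities[wl])


class TestDrift:
    def test_pure_ramp_recovered_exactly(self):
        m = ph.DriftModel(linear_rate_pct_per_h=1.0, white_sigma_frac=0.0,
                          flicker_sigma_frac=0.0)
        s = ph.drift_series(m, 3600.0, 5.0, seed=1)
        assert qc.linear_drift_rate(s, 5.0) == pytest.approx(1.0, abs=1e-6)

    def test_all_components_off_constant(self):
        m = ph.DriftModel(linear_rate_pct_per_h=0.0, white_sigma_frac=0.0,
                          flicker_sigma_frac=0.0)
        s = ph.drift_series(m, 3600.0, 5.0, seed=1)
        assert np.allclose(s, 1.0)
        dev = qc.allan_deviation(s, 5.0, [1.0, 10.0, 100.0])
        assert all(v == 0.0 for v in dev.values())

    def test_white_noise_allan_slope(self):
        m = ph.DriftModel(linear_rate_pct_per_h=0.0, white_sigma_frac=1e-3,
                          flicker_sigma_frac=0.0)
        s = ph.drift_series(m, 3600.0, 5.0, seed=2)
        taus = np.logspace(0, 2, 10)
        dev = qc.allan_deviation(s, 5.0, taus)
        x = np.log10(list(dev))
        y = np.log10([dev[t] for t in dev])
        slope, _ = np.polyfit(x, y, 1)
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_reproducible_and_self_consistent(self):
        m = ph.DriftModel()
        a = ph.drift_series(m, 3600.0, 5.0, seed=9)
        b = ph.drift_series(m, 3600.0, 5.0, seed=9)
        assert np.array_equal(a, b)
        fitted = qc.linear_drift_rate(a, 5.0)
        assert fitted == pytest.approx(m.linear_rate_pct_per_h, rel=0.10)
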