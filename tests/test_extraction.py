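"""ROI averaging, TDM demultiplexing, normalisation, saturation flags."""

import numpy as np
import pytest

from nirtwin import extraction as ext
from nirtwin.extraction import (ChannelTimeSeries, ROISpec, demultiplex,
                                flag_saturation, mean_gray_value,
                                normalize_by_source, rois_from_layout)
from nirtwin.sensor import Frame, SensorSpec, power_for_electrons, simulate_stream


def make_frame(data, slot=0, group=0):
    return Frame(data=np.asarray(data), timestamp_s=0.0, slot=slot, group=group)


class TestMeanGrayValue:
    def test_uniform_frame(self):
        roi = ROISpec(center_xy=(30.0, 30.0), radius_px=5,
                      wavelength_nm=695.0, detector_id=1)
        f = make_frame(np.full((64, 64), 17.0))
        assert mean_gray_value(f, roi) == 17.0

    def test_indicator_disc(self):
        roi = ROISpec(center_xy=(30.0, 30.0), radius_px=5,
                      wavelength_nm=695.0, detector_id=1)
        data = np.zeros((64, 64))
        gy, gx = np.mgrid[0:64, 0:64]
        data[(gx - 30) ** 2 + (gy - 30) ** 2 <= 25] = 100.0
        assert mean_gray_value(make_frame(data), roi) == 100.0

    def test_matches_exhaustive_enumeration(self, rng):
        roi = ROISpec(center_xy=(20.0, 25.0), radius_px=5,
                      wavelength_nm=695.0, detector_id=1)
        data = rng.integers(0, 4096, size=(64, 64)).astype(float)
        vals = [data[y, x] for y in range(64) for x in range(64)
                if (x - 20.0) ** 2 + (y - 25.0) ** 2 <= 25]
        assert mean_gray_value(make_frame(data), roi) == pytest.approx(
            np.mean(vals), rel=1e-12)

    def test_invariant_to_pixel_permutation(self, rng):
        roi = ROISpec(center_xy=(20.0, 20.0), radius_px=6,
                      wavelength_nm=695.0, detector_id=1)
        data = rng.uniform(0, 4095, size=(64, 64))
        before = mean_gray_value(make_frame(data), roi)
        rows, cols = roi.pixel_indices(64, 64)
        perm = rng.permutation(rows.size)
        data2 = data.copy()
        data2[rows, cols] = data[rows[perm], cols[perm]]
        assert mean_gray_value(make_frame(data2), roi) == pytest.approx(
            before, rel=1e-12)

    def test_out_of_bounds_rejected(self):
        roi = ROISpec(center_xy=(2.0, 30.0), radius_px=5,
                      wavelength_nm=695.0, detector_id=1)
        with pytest.raises(ValueError, match="bounds"):
            mean_gray_value(make_frame(np.zeros((64, 64))), roi)

    def test_pedestal_subtracted(self):
        roi = ROISpec(center_xy=(30.0, 30.0), radius_px=5,
                      wavelength_nm=695.0, detector_id=1)
        f = make_frame(np.full((64, 64), 150.0))
        assert mean_gray_value(f, roi, bias_adu=100.0) == 50.0


class TestDemultiplex:
    def run_constant(self, rig, levels_adu, n_cycles=4):
        sensor = rig.sensor
        n_px = rig.layout.n_pixels((1, 695.0))
        courses = {}
        for ch in rig.cmap.channels:
            for wl in (695.0, 830.0):
                level = levels_adu.get((ch.channel_id, wl), 300.0)
                p = power_for_electrons(level * sensor.conversion_gain, wl,
                                        sensor, n_pixels=n_px)
                courses[(ch.channel_id, wl)] = np.full(n_cycles, p)
        frames = simulate_stream(rig.schedule, rig.cmap, courses, sensor,
                                 rig.layout, 42)
        return frames, demultiplex(frames, rig.schedule, rig.cmap,
                                   rois_from_layout(rig.layout), sensor=sensor)

    def test_series_length_equals_cycles(self, small_rig):
        frames, series = self.run_constant(small_rig, {}, n_cycles=5)
        assert len(frames) == 5 * small_rig.schedule.n_groups
        for ts in series.values():
            assert ts.values.size == 5
            assert ts.sampling_rate_hz == small_rig.schedule.sampling_rate_hz

    def test_noiseless_left_inverse(self, noiseless_rig):
        levels = {}
        rng = np.random.default_rng(3)
        for ch in noiseless_rig.cmap.channels:
            for wl in (695.0, 830.0):
                levels[(ch.channel_id, wl)] = float(rng.uniform(50, 3000))
        _, series = self.run_constant(noiseless_rig, levels, n_cycles=2)
        for key, level in levels.items():
            assert series[key].values == pytest.approx(level, rel=1e-9)

    def test_power_ratio_recovered(self, small_rig):
        levels = {(1, 695.0): 400.0, (2, 695.0): 800.0}
        _, series = self.run_constant(small_rig, levels, n_cycles=6)
        ratio = series[(2, 695.0)].values.mean() / series[(1, 695.0)].values.mean()
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_missing_slot_yields_nan(self, small_rig):
        frames, _ = self.run_constant(small_rig, {}, n_cycles=3)
        dropped = [f for f in frames if f.slot != 1]
        with pytest.warns(UserWarning, match="missing slots"):
            series = demultiplex(dropped, small_rig.schedule, small_rig.cmap,
                                 rois_from_layout(small_rig.layout),
                                 sensor=small_rig.sensor)
        group1_channels = [ch.channel_id for ch in small_rig.cmap.channels
                           if small_rig.schedule.group_of_source[ch.source_id] == 1]
        assert group1_channels
        for cid in group1_channels:
            assert np.isnan(series[(cid, 695.0)].values[0])
            assert np.isfinite(series[(cid, 695.0)].values[1:]).all()

    def test_mislabelled_group_rejected(self, small_rig):
        frames, _ = self.run_constant(small_rig, {}, n_cycles=1)
        bad = [Frame(f.data, f.timestamp_s, f.slot, (f.group + 1)
                     % small_rig.schedule.n_groups) for f in frames]
        with pytest.raises(ValueError, match="tagged group"):
            demultiplex(bad, small_rig.schedule, small_rig.cmap,
                        rois_from_layout(small_rig.layout), sensor=small_rig.sensor)


class TestNormalize:
    def series_fixture(self, cmap33):
        return {(ch.channel_id, 695.0): ChannelTimeSeries(
            channel_id=ch.channel_id, wavelength_nm=695.0,
            values=np.full(4, 100.0), sampling_rate_hz=5.0)
            for ch in cmap33.channels}

    def test_equal_powers_uniform_scale(self, cmap33):
        series = self.series_fixture(cmap33)
        powers = {sid: 4.0 for sid in cmap33.grid.source_ids.values()}
        out = normalize_by_source(series, cmap33, powers)
        for ts in out.values():
            assert np.allclose(ts.values, 25.0)

    def test_invariant_to_global_rescale(self, cmap33):
        series = self.series_fixture(cmap33)
        p1 = {sid: 2.0 for sid in cmap33.grid.source_ids.values()}
        p2 = {sid: 4.0 for sid in cmap33.grid.source_ids.values()}
        a = normalize_by_source(series, cmap33, p1)
        b = normalize_by_source(series, cmap33, p2)
        for key in a:
            assert np.allclose(a[key].values, 2.0 * b[key].values)

    def test_zero_power_rejected(self, cmap33):
        series = self.series_fixture(cmap33)
        powers = {sid: 4.0 for sid in cmap33.grid.source_ids.values()}
        powers[1] = 0.0
        with pytest.raises(ValueError, match="source 1"):
            normalize_by_source(series, cmap33, powers)


class TestSaturation:
    def make(self, values):
        return ChannelTimeSeries(channel_id=1, wavelength_nm=695.0,
                                 values=np.asarray(values, float),
                                 sampling_rate_hz=5.0)

    def test_no_flags_below_ceiling(self):
        rep = flag_saturation(self.make([100, 4094, 2000]))
        assert not rep.flags.any() and not rep.warn

    def test_single_sample_at_ceiling(self):
        rep = flag_saturation(self.make([100, 4095, 2000]))
        assert rep.flags.tolist() == [False, True, False]
        assert rep.warn  # 33% > 0.1%

    def test_fraction_matches_count(self, rng):
        values = rng.choice([1000.0, 4095.0], size=500, p=[0.9, 0.1])
        rep = flag_saturation(self.make(values))
        assert rep.fraction == pytest.approx(np.mean(values == 4095.0))
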