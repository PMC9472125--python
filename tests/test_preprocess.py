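"""Filters, resampling, Beer–Lambert inversion, labeling, rejection,
normalization."""

import numpy as np
import pytest
from scipy import signal as sig

from neurorp.core_io import ChannelInfo, Recording
from neurorp.preprocess import (
    bandpass_zero_phase,
    fit_normalizer,
    label_segments,
    lowpass_zero_phase,
    mbll_convert,
    normalize,
    reject_outliers,
    resample,
)
from neurorp.synthgen import build_schedule

from conftest import make_eeg_recording


def _sine(freq, rate, duration_s=60.0):
    t = np.arange(int(duration_s * rate)) / rate
    return make_eeg_recording(np.sin(2 * np.pi * freq * t)[None, :], rate)


def _amplitude_at(x, rate, freq):
    """Lock-in amplitude estimate of one frequency component (edges trimmed)."""
    n = x.size
    trim = n // 10
    x = x[trim : n - trim]
    t = np.arange(x.size) / rate + trim / rate
    c = 2 * np.mean(x * np.cos(2 * np.pi * freq * t))
    s = 2 * np.mean(x * np.sin(2 * np.pi * freq * t))
    return float(np.hypot(c, s))


class TestResample:
    def test_eeg_downsample_rate(self, rng):
        rec = make_eeg_recording(rng.standard_normal((2, 10000)), 1000.0)
        out = resample(rec, 200.0)
        assert out.rate == 200.0
        assert abs(out.duration - rec.duration) <= 1.0 / 200.0

    def test_identity_when_rate_matches(self, rng):
        rec = make_eeg_recording(rng.standard_normal((2, 1000)), 200.0)
        out = resample(rec, 200.0)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_upsampling_refused(self, rng):
        rec = make_eeg_recording(rng.standard_normal((1, 100)), 10.0)
        with pytest.raises(ValueError, match="upsampling"):
            resample(rec, 20.0)

    def test_sub_nyquist_tone_survives_downsampling(self):
        rec = _sine(80.0, 1000.0, duration_s=20.0)
        out = resample(rec, 200.0)
        f, p = sig.periodogram(out.data[0], fs=200.0)
        assert abs(f[np.argmax(p)] - 80.0) < 0.5
        amp = _amplitude_at(out.data[0], 200.0, 80.0)
        assert abs(amp - 1.0) < 0.05

    def test_fnirs_fractional_ratio(self, rng):
        rec = make_eeg_recording(rng.standard_normal((1, 1040)), 10.4)
        out = resample(rec, 10.0)
        assert np.isclose(out.rate, 10.0)
        assert out.n_samples == 1000


class TestZeroPhaseFilters:
    def test_dc_offset_removed_by_bandpass(self):
        rec = make_eeg_recording(np.full((1, 5000), 10.0), 200.0)
        out = bandpass_zero_phase(rec)
        assert abs(out.data.mean()) < 1e-6 * 10.0

    def test_passband_tone_preserved(self):
        out = bandpass_zero_phase(_sine(20.0, 200.0))
        assert abs(_amplitude_at(out.data[0], 200.0, 20.0) - 1.0) < 0.02

    def test_stopband_attenuation_matches_squared_butterworth(self):
        # analytic two-pass attenuation at 50 Hz for the 1-40 Hz 6th-order design
        out = bandpass_zero_phase(_sine(50.0, 200.0))
        amp = _amplitude_at(out.data[0], 200.0, 50.0)
        sos = sig.butter(6, [1, 40], btype="bandpass", fs=200.0, output="sos")
        _, h = sig.sosfreqz(sos, worN=[50.0], fs=200.0)
        expected_db = -2 * 20 * np.log10(np.abs(h[0]))
        measured_db = -20 * np.log10(amp)
        assert abs(measured_db - expected_db) < 1.0

    def test_lowpass_dc_and_passband(self):
        rec = make_eeg_recording(np.full((1, 600), 3.0), 10.0)
        out = lowpass_zero_phase(rec)
        np.testing.assert_allclose(out.data, 3.0, rtol=1e-9)
        out2 = lowpass_zero_phase(_sine(0.05, 10.0, duration_s=600.0))
        assert abs(_amplitude_at(out2.data[0], 10.0, 0.05) - 1.0) < 0.02

    def test_lowpass_stopband_attenuation(self):
        out = lowpass_zero_phase(_sine(1.0, 10.0, duration_s=600.0))
        amp = _amplitude_at(out.data[0], 10.0, 1.0)
        assert -20 * np.log10(max(amp, 1e-30)) >= 80.0

    def test_zero_lag_between_input_and_output(self):
        """Cross-correlation of a band-limited tone peaks at lag 0."""
        rec = _sine(10.0, 200.0, duration_s=30.0)
        out = bandpass_zero_phase(rec)
        x, y = rec.data[0], out.data[0]
        lags = sig.correlation_lags(x.size, y.size)
        xc = sig.correlate(x, y)
        assert lags[np.argmax(xc)] == 0

    def test_band_outside_nyquist_rejected(self):
        rec = _sine(10.0, 60.0, duration_s=10.0)
        with pytest.raises(ValueError):
            bandpass_zero_phase(rec, 1.0, 40.0)  # 40 Hz > 30 Hz Nyquist


class TestMBLL:
    def _od(self, data, wavelengths=(760.0, 850.0), distance=3.0):
        chans = [
            ChannelInfo(
                label=f"S1_D1 {w:.0f}nm", role="sd_pair", wavelength=w,
                source_detector_distance=distance,
            )
            for w in wavelengths
        ]
        return Recording(data=data, rate=10.0, channels=chans, modality="fnirs_od")

    def test_zero_od_gives_zero_concentrations(self):
        hemo = mbll_convert(self._od(np.zeros((2, 10))))
        assert np.allclose(hemo.hbo, 0) and np.allclose(hemo.hbr, 0)

    def test_identity_extinction_passes_od_through(self):
        od = self._od(np.array([[0.5], [0.25]]), distance=1.0)
        ext = {760.0: (1.0, 0.0), 850.0: (0.0, 1.0)}
        hemo = mbll_convert(od, extinction=ext, dpf=1.0)
        assert np.isclose(hemo.hbo[0, 0], 0.5)
        assert np.isclose(hemo.hbr[0, 0], 0.25)

    def test_singular_extinction_reports_condition_number(self):
        od = self._od(np.zeros((2, 4)))
        ext = {760.0: (1.0, 1.0), 850.0: (1.0, 1.0 + 1e-12)}
        with pytest.raises(ValueError, match="condition number"):
            mbll_convert(od, extinction=ext)

    def test_mean_baseline_option_recenters(self):
        data = np.vstack([np.linspace(0, 1, 11), np.linspace(0, 2, 11)])
        hemo = mbll_convert(self._od(data), baseline="mean")
        assert abs(hemo.hbo.mean()) < 1e-12


class TestLabeling:
    def test_default_protocol_segment_counts(self, default_schedules):
        segs = label_segments(default_schedules)
        assert len(segs) == 54
        for cond in ("0-back", "2-back", "3-back"):
            assert len(segs.by_label(cond)) == 9
        assert len(segs.by_label("rest")) == 27

    def test_one_series_yields_one_task_one_rest(self, tiny_protocol):
        segs = label_segments(build_schedule(tiny_protocol, 0)[:1])
        assert len(segs) == 2

    def test_empty_schedule(self):
        from neurorp.core_io import EventSchedule

        assert len(label_segments(EventSchedule(events=[]))) == 0

    def test_instruction_periods_excluded(self, default_schedules):
        segs = label_segments(default_schedules)
        starts = {s.start for s in segs.segments}
        for sched in default_schedules:
            assert sched.events[0].onset not in starts  # instruction onset


class TestOutliersAndNormalization:
    def test_clean_windows_all_kept(self, rng):
        w = rng.standard_normal((20, 4, 100))
        kept, log = reject_outliers(w, z_max=5.0)
        assert kept.shape == w.shape and log["n_rejected"] == 0

    def test_spiked_window_rejected(self, rng):
        w = rng.standard_normal((20, 4, 100))
        mad = np.median(np.abs(w - np.median(w)))
        w[7, 2, 50] = 50 * mad / 0.01  # enormous spike
        kept, log = reject_outliers(w, z_max=5.0)
        assert log["rejected_indices"] == [7]
        assert kept.shape[0] == 19

    def test_infinite_threshold_is_identity(self, rng):
        w = rng.standard_normal((5, 2, 10)) * 100
        kept, log = reject_outliers(w, z_max=np.inf)
        np.testing.assert_array_equal(kept, w)

    def test_all_rejected_raises(self):
        w = np.zeros((3, 1, 5))
        w[:, 0, 2] = [1e6, -1e6, 1e6]
        with pytest.raises(ValueError, match="review"):
            reject_outliers(np.abs(w) + np.arange(5) * 1e6, z_max=0.0)

    def test_training_statistics_standardize_training_data(self, rng):
        w = rng.standard_normal((30, 3, 50)) * 4 + 2
        stats = fit_normalizer(w)
        z = normalize(w, stats)
        np.testing.assert_allclose(z.mean(axis=(0, 2)), 0, atol=1e-10)
        np.testing.assert_allclose(z.std(axis=(0, 2)), 1, atol=1e-10)

    def test_train_stats_applied_to_shifted_copy(self, rng):
        w = rng.standard_normal((30, 2, 50))
        stats = fit_normalizer(w)
        shifted = normalize(w + 5.0, stats)
        expected = 5.0 / stats[1]
        np.testing.assert_allclose(
            shifted.mean(axis=(0, 2)), expected, atol=1e-10
        )

    def test_zero_variance_channel_named(self):
        w = np.zeros((4, 2, 10))
        w[:, 0] = np.random.default_rng(0).standard_normal((4, 10))
        with pytest.raises(ValueError, match=r"\[1\]"):
            fit_normalizer(w)

    def test_disjoint_folds_get_disjoint_statistics(self, rng):
        a = rng.standard_normal((10, 2, 20))
        b = rng.standard_normal((10, 2, 20)) + 10
        sa, sb = fit_normalizer(a), fit_normalizer(b)
        assert not np.allclose(sa[0], sb[0])
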