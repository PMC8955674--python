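"""Tachogram interpolation, Welch normalization, and band-power integration."""

import numpy as np
import pytest

import murihrv as m


class TestTachogram:
    def test_constant_series_gives_constant_tachogram(self, series_factory):
        tach = m.build_tachogram(series_factory([100.0] * 100))
        np.testing.assert_allclose(tach.values, 100.0, atol=1e-9)
        assert tach.sampling_rate == 10.0

    def test_slow_sinusoid_interpolated_accurately(self):
        # knots every ~100 ms on a 0.2 Hz modulated interval signal
        t = np.arange(1, 600) * 0.1
        vals = 100 + 5 * np.sin(2 * np.pi * 0.2 * t)
        s = m.RRISeries(intervals=vals, beat_times=t)
        tach = m.build_tachogram(s)
        grid = tach.start_time + np.arange(len(tach)) / tach.sampling_rate
        analytic = 100 + 5 * np.sin(2 * np.pi * 0.2 * grid)
        assert np.max(np.abs(tach.values - analytic)) < 0.1

    def test_no_extrapolation(self, series_factory):
        s = series_factory([100.0] * 50)
        tach = m.build_tachogram(s)
        end = tach.start_time + (len(tach) - 1) / tach.sampling_rate
        assert tach.start_time == pytest.approx(s.beat_times[0])
        assert end <= s.beat_times[-1] + 1e-12

    def test_fewer_than_four_intervals_rejected(self, series_factory):
        with pytest.raises(m.InsufficientDataError):
            m.build_tachogram(series_factory([100.0] * 3))


class TestWelch:
    def test_parseval_on_white_noise(self, rng):
        for _ in range(5):
            x = rng.normal(0, 3.0, size=4096)
            tach = m.Tachogram(values=x, sampling_rate=10.0)
            spec = m.welch_psd(tach)
            integral = np.trapezoid(spec.psd, spec.frequencies)
            assert integral == pytest.approx(np.var(x), rel=0.05)

    def test_sinusoid_power_localized(self):
        t = np.arange(8192) / 10.0
        a = 4.0
        tach = m.Tachogram(values=a * np.sin(2 * np.pi * 2.0 * t), sampling_rate=10.0)
        spec = m.welch_psd(tach)
        peak = spec.frequencies[np.argmax(spec.psd)]
        df = spec.frequencies[1] - spec.frequencies[0]
        assert abs(peak - 2.0) <= df
        assert m.band_power(spec, (1.8, 2.2)) == pytest.approx(a**2 / 2, rel=0.10)

    def test_zero_signal_zero_psd(self):
        tach = m.Tachogram(values=np.zeros(1024), sampling_rate=10.0)
        spec = m.welch_psd(tach)
        assert np.all(spec.psd == 0.0)

    def test_segment_longer_than_record_rejected(self):
        tach = m.Tachogram(values=np.zeros(100), sampling_rate=10.0)
        with pytest.raises(m.InsufficientDataError):
            m.welch_psd(tach)


class TestBandPower:
    @staticmethod
    def _flat(level=1.0, fmax=5.0, n=501):
        f = np.linspace(0.0, fmax, n)
        return m.SpectralEstimate(frequencies=f, psd=np.full(n, level))

    def test_rectangles(self):
        spec = self._flat()
        assert m.band_power(spec, (0.1, 1.0)) == pytest.approx(0.9)
        assert m.band_power(spec, (1.0, 4.0)) == pytest.approx(3.0)

    def test_pro_rata_edges(self):
        # band edges between bins still integrate exactly on a flat spectrum
        spec = self._flat(level=2.0, n=26)
        assert m.band_power(spec, (0.333, 1.777)) == pytest.approx(2.0 * (1.777 - 0.333))

    def test_additivity(self):
        spec = self._flat(level=1.3)
        total = m.band_power(spec, (0.1, 4.0))
        parts = m.band_power(spec, (0.1, 1.0)) + m.band_power(spec, (1.0, 4.0))
        assert total == pytest.approx(parts, rel=1e-9)

    def test_inverted_band_rejected(self):
        with pytest.raises(m.ConfigurationError):
            m.band_power(self._flat(), (2.0, 1.0))


class TestFreqMetrics:
    @staticmethod
    def _series(lf_amp=0.0, hf_amp=0.0, lf_freq=0.4, hf_freq=2.0, seed=0):
        cfg = m.RRSynthConfig(mean_rr=100, lf_amp=lf_amp, lf_freq=lf_freq,
                              hf_amp=hf_amp, hf_freq=hf_freq, jitter_sd=0,
                              duration=300, seed=seed)
        s, _ = m.generate_rri(cfg)
        return s

    def test_hf_only_modulation_lands_in_hf_band(self):
        fd = m.freq_metrics(self._series(hf_amp=5.0))
        assert fd.hf_power / (fd.lf_power + fd.hf_power) > 0.8

    def test_lf_only_modulation_lands_in_lf_band(self):
        fd = m.freq_metrics(self._series(lf_amp=5.0))
        assert fd.lf_power / (fd.lf_power + fd.hf_power) > 0.8

    def test_constant_series_has_no_band_power(self, series_factory):
        fd = m.freq_metrics(series_factory([100.0] * 3000))
        assert fd.lf_power < 1e-6 and fd.hf_power < 1e-6

    def test_band_power_scales_quadratically_with_amplitude(self):
        p1 = m.freq_metrics(self._series(hf_amp=2.0)).hf_power
        p2 = m.freq_metrics(self._series(hf_amp=4.0)).hf_power
        assert p2 / p1 == pytest.approx(4.0, rel=0.10)

    def test_band_powers_invariant_to_mean_level(self):
        a = self._series(hf_amp=3.0)
        b = m.RRISeries(intervals=a.intervals + 40.0,
                        beat_times=a.beat_times, labels=a.labels)
        fa = m.freq_metrics(a)
        fb = m.freq_metrics(b)
        assert fb.hf_power == pytest.approx(fa.hf_power, rel=0.02)

    def test_ratio_positive_when_both_bands_have_power(self):
        fd = m.freq_metrics(self._series(lf_amp=3.0, hf_amp=3.0))
        assert fd.lf_hf > 0
        assert fd.lf_hf == pytest.approx(fd.lf_power / fd.hf_power)
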