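"""Generator correctness: IPFM beat timing, spectra, waveform ground truth."""

import numpy as np
import pytest

import murihrv as m
from murihrv.hrv_freq import build_tachogram


class TestGenerateRRI:
    def test_constant_process_is_deterministic(self):
        s, truth = m.generate_rri(
            m.RRSynthConfig(mean_rr=100, lf_amp=0, hf_amp=0, jitter_sd=0, duration=1)
        )
        assert s.n == 10
        np.testing.assert_allclose(s.intervals, 100.0)
        np.testing.assert_allclose(truth.beat_times, np.arange(11) * 0.1)

    def test_sinusoidal_modulation_preserves_mean(self):
        # zero-mean sinusoid sampled over many cycles cannot shift the mean
        s, _ = m.generate_rri(
            m.RRSynthConfig(mean_rr=100, lf_amp=0, hf_amp=5, hf_freq=2.0,
                            jitter_sd=0, duration=180)
        )
        assert abs(np.mean(s.intervals) - 100.0) < 0.5

    def test_spans_at_least_duration(self):
        cfg = m.RRSynthConfig(mean_rr=137, jitter_sd=3, duration=47, seed=5)
        _, truth = m.generate_rri(cfg)
        assert truth.beat_times[-1] >= cfg.duration

    def test_identical_seeds_bit_identical(self):
        cfg = m.RRSynthConfig(jitter_sd=3, duration=30, seed=77)
        s1, t1 = m.generate_rri(cfg)
        s2, t2 = m.generate_rri(cfg)
        assert np.array_equal(s1.intervals, s2.intervals)
        assert np.array_equal(t1.beat_times, t2.beat_times)

    def test_positivity_over_random_valid_configs(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            mean_rr = rng.uniform(60, 200)
            lf = rng.uniform(0, mean_rr / 5)
            hf = rng.uniform(0, mean_rr / 5)
            jitter = rng.uniform(0, (mean_rr - lf - hf) / 4.01 * 0.99)
            cfg = m.RRSynthConfig(
                mean_rr=mean_rr, lf_amp=lf, hf_amp=hf, jitter_sd=jitter,
                lf_freq=rng.uniform(0.11, 0.99), hf_freq=rng.uniform(1.01, 3.99),
                duration=3.0, seed=int(rng.integers(2**31)),
            )
            s, _ = m.generate_rri(cfg)
            assert np.all(s.intervals > 0)

    @pytest.mark.parametrize("bad", [
        dict(mean_rr=-5),
        dict(duration=0),
        dict(jitter_sd=-1),
        dict(lf_amp=2, lf_freq=1.5),
        dict(hf_amp=2, hf_freq=0.5),
        dict(mean_rr=100, lf_amp=60, hf_amp=50, jitter_sd=0),
    ])
    def test_invalid_config_raises(self, bad):
        with pytest.raises(m.ConfigurationError):
            m.RRSynthConfig(**bad)

    @pytest.mark.parametrize("lf_amp,hf_amp,freq_key,freq", [
        (4.0, 0.0, "lf_freq", 0.4),
        (0.0, 4.0, "hf_freq", 2.0),
    ])
    def test_modulation_power_concentrates_at_set_frequency(self, lf_amp, hf_amp, freq_key, freq):
        cfg = m.RRSynthConfig(mean_rr=100, lf_amp=lf_amp, hf_amp=hf_amp,
                              jitter_sd=0, duration=300, **{freq_key: freq})
        s, _ = m.generate_rri(cfg)
        tach = build_tachogram(s, rate=10.0)
        x = tach.values - tach.values.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(len(x), 1 / 10.0)
        inband = spec[(f >= freq - 0.1) & (f <= freq + 0.1)].sum()
        assert inband / spec[f > 0].sum() >= 0.90


class TestGenerateECG:
    def test_noiseless_maxima_at_truth_times(self):
        s, _ = m.generate_rri(m.RRSynthConfig(mean_rr=100, lf_amp=0, hf_amp=0,
                                              jitter_sd=0, duration=5))
        rec, truth = m.generate_ecg(s, m.ECGSynthConfig())
        fs = rec.sampling_rate
        for bt in truth.beat_times:
            i = int(round(bt * fs))
            lo, hi = max(0, i - 60), i + 60
            assert abs(np.argmax(rec.samples[lo:hi]) + lo - i) == 0

    def test_truth_times_within_one_sample_of_r_centers(self):
        s, _ = m.generate_rri(m.RRSynthConfig(mean_rr=110, jitter_sd=2, duration=10, seed=3))
        rec, truth = m.generate_ecg(s, m.ECGSynthConfig())
        # R centers are the synth beat times plus the 0.1 s lead-in
        centers = np.concatenate([[s.start_time], s.beat_times]) + 0.1
        assert np.max(np.abs(truth.beat_times - centers)) <= 1.0 / rec.sampling_rate

    def test_empty_series_gives_flat_baseline(self):
        empty = m.RRISeries(intervals=np.array([]), beat_times=np.array([]))
        rec, truth = m.generate_ecg(empty, m.ECGSynthConfig())
        assert truth.beat_times.size == 0
        assert np.allclose(rec.samples, 0.0)

    def test_non_dominant_r_rejected(self):
        template = ((1.0, 0.0, 5.0), (1.0, 10.0, 5.0))
        with pytest.raises(m.ConfigurationError):
            m.ECGSynthConfig(template_params=template)

    def test_undersampled_template_rejected(self):
        s, _ = m.generate_rri(m.RRSynthConfig(duration=2))
        with pytest.raises(m.ConfigurationError):
            m.generate_ecg(s, m.ECGSynthConfig(sampling_rate=500.0))

    def test_seeded_noise_reproducible(self):
        s, _ = m.generate_rri(m.RRSynthConfig(duration=3))
        cfg = m.ECGSynthConfig(noise_sd=0.1, seed=9)
        r1, _ = m.generate_ecg(s, cfg)
        r2, _ = m.generate_ecg(s, cfg)
        assert np.array_equal(r1.samples, r2.samples)


class TestCohortProfiles:
    def test_naive_profile_recovers_printed_mean_rri(self):
        """Downstream mean RRI lands within 2% of the healthy-cohort setting."""
        cfg = m.synth_ecg.profile_config(m.NAIVE_PROFILE, duration=300, seed=4)
        s, _ = m.generate_rri(cfg)
        win = m.window_rri(s, m.WindowSpec())
        assert abs(m.mean_rri(win) - 135.8685) / 135.8685 < 0.02

    def test_jitter_solver_round_trips(self):
        sd = m.jitter_for_rmssd(11.13, 135.9, lf_amp=2.0, hf_amp=3.0)
        cfg = m.RRSynthConfig(mean_rr=135.9, lf_amp=2.0, hf_amp=3.0,
                              jitter_sd=sd, duration=600, seed=8)
        s, _ = m.generate_rri(cfg)
        assert abs(m.rmssd(s) - 11.13) / 11.13 < 0.10

    def test_cohort_configs_respect_invariants(self):
        for profile in (m.NAIVE_PROFILE, m.CANCER_PROFILE):
            cfgs = m.cohort_configs(profile, 25, duration=10, seed=1)
            assert len(cfgs) == 25  # construction itself validates invariants
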