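# murihrv

Heart-rate-variability (HRV) analysis for mouse electrocardiograms, built for
studies that track autonomic change — for example visceral cancer pain in a
peritoneal-metastasis model — through telemetry ECG and welfare scoring.

Mouse hearts beat at 500–700 bpm, so human HRV tooling does not transfer: QRS
complexes are ~10 ms wide, R-R intervals sit near 100 ms, and the
autonomic modulation bands shift up to 0.1–1.0 Hz (LF) and 1.0–4.0 Hz (HF).
`murihrv` implements the full chain with mouse-scale parameters:

1. **Preprocessing** — zero-phase 3rd-order Butterworth bandpass (0.5–50 Hz)
   and anti-aliased decimation of high-rate telemetry (e.g. 32 kHz → 2 kHz).
2. **R-peak detection** — a Pan–Tompkins-style detector (derivative, squaring,
   12 ms moving-window integration, adaptive dual thresholds with search-back,
   30 ms refractory period) with peak refinement on the filtered ECG so beat
   timing is accurate to well under a millisecond.
3. **RR-interval processing** — interval construction, a 3-minute analysis
   window, and artifact screening.
4. **HRV metrics** — time domain: mean RRI, RMSSD
   (√(Σ(RRᵢ₊₁−RRᵢ)²/(N−1))) and pNN5 (the rodent analogue of pNN50);
   frequency domain: 10 Hz cubic-spline tachogram, Welch power spectral
   density, LF/HF band powers and their ratio.
5. **Pain scoring** — a four-category welfare rubric (physiological signs,
   posture, appearance, activity) yielding a 0–4 score per animal.
6. **Group statistics** — Mann–Whitney U (exact for small tie-free samples),
   Kruskal–Wallis with Bonferroni-corrected pairwise post hocs, mean ± SEM
   summaries.
7. **Synthetic data** — an integral-pulse-frequency-modulation (IPFM) RR
   generator and a Gaussian-template PQRST waveform synthesizer with exact
   ground truth, so every stage is testable without animal data.

## Worked example

Simulate five minutes of noisy mouse ECG with known beat times, then run the
full pipeline:

```python
import murihrv as m

gen = m.RRSynthConfig(mean_rr=100.0, lf_amp=2.0, lf_freq=0.4,
                      hf_amp=3.0, hf_freq=2.5, jitter_sd=2.0,
                      duration=300.0, seed=42)
rri, _ = m.generate_rri(gen)
ecg, truth = m.generate_ecg(rri, m.ECGSynthConfig(noise_sd=0.1, seed=42))

peaks = m.detect_rpeaks(m.bandpass(ecg))
sens, ppv, err = m.match_to_truth(peaks, truth, tol=5.0)
print(f"beats: {len(peaks)}  sensitivity: {sens:.4f}  ppv: {ppv:.4f}")

series = m.window_rri(m.peaks_to_rri(peaks), m.WindowSpec(duration=180.0))
series = m.screen_artifacts(series)
td = m.time_domain_metrics(series)
fd = m.freq_metrics(series)
print(f"mean RRI: {td.mean_rri:.2f} ms   RMSSD: {td.rmssd:.2f} ms   pNN5: {td.pnn5:.1f} %")
print(f"LF: {fd.lf_power:.3f} ms^2  HF: {fd.hf_power:.3f} ms^2  LF/HF: {fd.lf_hf:.2f}")
```

which prints:

```
beats: 3005  sensitivity: 1.0000  ppv: 1.0000
mean RRI: 99.85 ms   RMSSD: 4.14 ms   pNN5: 22.9 %
LF: 2.997 ms^2  HF: 6.206 ms^2  LF/HF: 0.48
```

All 3005 synthetic beats were found (none missed, none spurious), the mean
R-R interval of the central 3-minute window recovers the configured 100 ms to
0.15%, and the observed RMSSD matches the analytic expectation for 2 ms white
jitter plus the configured sinusoidal modulation
(√(2σ² + Σ 2a²sin²(πfT̄)) = √17.1 ≈ 4.1 ms). Band powers land in the configured bands: the 2.5 Hz
modulation drives HF, the 0.4 Hz modulation drives LF.

A command-line interface wraps the same pipeline:

```sh
murihrv simulate --profile naive          # synthetic recording + ground truth
murihrv analyze recording.txt             # one subject -> HRV metrics
murihrv study manifest.csv                # whole study -> tables + tests
murihrv painscore observations.csv        # welfare rubric scores
```

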