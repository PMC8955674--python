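# Methods

## Scope and model

`murihrv` analyzes single-channel mouse ECG for heart-rate variability and
pairs it with a welfare-based pain rubric and nonparametric group statistics.
The analysis chain is: bandpass filtering → R-peak detection → R-R interval
(RRI) series → 3-minute analysis window → artifact screening → time-domain
metrics (mean RRI, RMSSD, pNN5) and frequency-domain metrics (LF, HF, LF/HF,
total power from a Welch spectrum of a 10 Hz cubic-spline tachogram).
Conventions used throughout: times in seconds, intervals in milliseconds,
voltages in millivolts; an interval is indexed by the beat that *ends* it;
analysis windows are half-open `[t0, t0 + duration)` over ending beat times.

## Synthetic data generator

Real murine telemetry for this kind of study is rarely shareable, so the
package carries a generator with exact ground truth.

**RR process.** An interval-sampling approximation of integral pulse
frequency modulation (IPFM): the instantaneous interval signal is

    RR(t) = mean_rr + lf_amp·sin(2π·lf_freq·t) + hf_amp·sin(2π·hf_freq·t)

and the i-th interval equals RR evaluated at the (i−1)-th beat time plus
independent Gaussian beat-to-beat jitter (truncated at ±4σ so the configured
invariant `lf_amp + hf_amp + 4·jitter_sd < mean_rr` guarantees strictly
positive intervals). This scheme is exactly invertible — the generator
returns the true beat times and intervals — and at murine modulation depths
(a few ms on ~100 ms) it is indistinguishable from threshold-crossing IPFM.
For a sinusoid of amplitude `a` at frequency `f` sampled every `T ≈ mean_rr`,
the expected squared successive difference is `2a²sin²(πfT)`; white jitter
adds `2σ²`. `jitter_for_rmssd` inverts this to hit a requested RMSSD.

**Waveform.** One five-Gaussian PQRST template per beat (component widths are
FWHM in ms; default R: 1 mV, 5 ms — rodent-scale QRS), plus optional
single-tone baseline wander (0.3 Hz) and white Gaussian noise. SNR in dB is
defined as R amplitude over noise SD. The record carries a 0.1 s baseline
lead-in/out: a trace that begins at an R apex is unphysical and, under
zero-phase filtering, produces a reflection transient large enough to poison
detector-threshold bootstrapping. Default sampling rate is 2 kHz (0.5 ms
timing grain, ample for a 50 Hz analysis band); telemetry-grade rates such as
32 kHz are supported and decimated on ingestion.

**Cohort profiles.** Two day-12 profiles describe a healthy cohort
(mean RR 135.87 ms, RMSSD 11.13 ms) and a tumor-bearing cohort
(mean RR 98.69 ms, RMSSD 3.60 ms), with modulation amplitudes of a few ms
(reduced in the sick cohort, matching vagal withdrawal). Two sampling modes
exist: *means-as-settings* (every subject's generator uses the profile means;
subjects differ only by seed), used for qualitative direction-of-effect
checks; and *subject variation* (the default for demos), which draws
subject-level mean RR and RMSSD around the profile means with study-scale
SDs (group SEM·√n) and couples the two perturbations through a latent
"autonomic severity" factor with loading 0.7 — vagal withdrawal shortens
intervals and suppresses variability together. RMSSD draws are floored at
the deterministic-modulation floor.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: ectopic beats, electrode drop-out and movement
artifact, powerline and EMG noise, circadian or temperature-driven
nonstationarity, respiratory-rate variation (HF is a fixed tone, not a band),
and any nonlinear RR dynamics. Detector and recovery results on synthetic
records are best-case bounds, not field performance claims.

## Preprocessing

3rd-order Butterworth bandpass, 0.5–50 Hz, applied forward–backward
(`sosfiltfilt`, effective magnitude order 6). Zero phase is essential: every
HRV metric consumes R-peak *timing*, and causal filtering shifts peaks.
Reflect padding of three low-cut time constants (3·fs/low_cut samples)
suppresses edge transients; the first/last 0.5 s are still considered
transient-prone and the detector avoids them when bootstrapping thresholds.
A 0.5–50 Hz passband is narrow for mouse QRS energy (fundamental ~10 Hz with
harmonics well past 50 Hz) and roughly halves R amplitude; detection still
works because thresholds are relative, and the band is config-overridable.
Decimation is polyphase rational resampling (anti-aliased FIR), applied
automatically above 4 kHz down to the 2 kHz working rate.

## R-peak detection

A Pan–Tompkins-style detector with mouse-scale constants: five-point
derivative, squaring, 12 ms moving-window integration (≈ rodent QRS width;
the classic human detector uses 150 ms), adaptive dual thresholds with
exponential running levels (coefficient 0.125), a 30 ms refractory period
(guards against double-counting while admitting heart rates to ~2000 bpm),
and search-back at a lowered threshold when the gap since the last accepted
beat exceeds 1.66× the running mean RR. Each accepted peak is then refined to
the local maximum of the filtered ECG within ±10 ms (integrated-signal peaks
lag true R by the integration window; plateau ties resolve to the earliest
sample).

Four design choices depart from the textbook recipe:

* **Threshold bootstrap** uses the first 2 s (signal level 0.7·max,
  noise level 0.5·mean of the integrated signal), skipping the 0.5 s edge
  region; a **second pass** then re-runs the adaptive selection with levels
  initialized from the settled accepted/rejected medians of the first pass.
  The one-pass bootstrap systematically over-thresholds the first ~1.5 s and
  silently drops those beats.
* **Polarity** is resolved by running the detector on the signal and its
  negation and keeping the orientation whose refined peaks sit on the larger
  median deflection. Peak *count* cannot arbitrate: squaring makes the
  integrated signal polarity-blind, so both orientations accept nearly the
  same beats, and the wrong orientation can even accept more (its refinement
  lands on distinct noise bumps instead of collapsing onto shared R apexes).
* **Beat-free gate**: a record is declared beat-free when the median accepted
  integrated-peak energy is less than 4.5× the median rejected energy.
  Band-limited white noise scores ≈ 3.7 on this ratio and ECG at usable SNR
  ≥ 5.4, so the gate rejects noise-only records (zero false beats) without
  touching degraded-but-real recordings.
* Thresholds are all relative to the data, making detection invariant to
  positive amplitude rescaling.

Detector scoring (`match_to_truth`) uses greedy one-to-one nearest matching
within ±5 ms; sensitivity = matched/truth, PPV = matched/detections.

## RRI processing and HRV metrics

The default analysis window is the centered 3 minutes of a 5-minute
recording (edges of a handling session are the most stress- and
artifact-prone). Screening flags intervals outside 50–300 ms or jumping more
than 30% from the previous retained interval; both bounds are permissive
(sinus mouse RRIs rarely leave 80–160 ms) and screening can be disabled.
Excluded intervals never contribute to any metric, and successive-difference
metrics (RMSSD, pNN5) only use adjacent retained pairs with no exclusion
between them; the RMSSD denominator is the number of pairs actually used.
pNN5 uses the absolute successive difference with a strict `>5 ms` rule; a
signed variant is available by configuration since both definitions appear in
the literature.

The tachogram is a natural cubic spline through (ending-beat-time, interval)
knots evaluated on a uniform 10 Hz grid, never extrapolating. Welch defaults:
512-sample segments (51.2 s → ≈0.02 Hz resolution, resolving the 0.1 Hz LF
edge), 50% overlap, Hann window, mean detrend; one-sided density
normalization is Parseval-consistent (integral ≈ variance). Band powers are
trapezoidal integrals with pro-rata edge bins; LF = [0.1, 1.0) Hz,
HF = [1.0, 4.0] Hz (the shared edge belongs to HF — numerically negligible
under pro-rata splitting); total power is the integral over 0.1–4.0 Hz, the
union of the defined bands. LF/HF is flagged NaN when HF power is zero.

## Pain rubric

Four categories, each 0/1, summing to 0–4: physiological (body-weight change
strictly greater than 10% versus the previous measurement — skipped on a
first observation, body temperature outside 35.8–37.4 °C, or
diarrhea/bloody stool), posture (hunched), appearance (rough coat, pinched
face, distended abdomen, or reluctance to move), and activity (any gap longer
than 30 s between consecutive movement/grooming events in a 5-minute
observation, counting the boundaries: an animal inactive for the first 40 s
scores the point). Temperature scores on deviation in *either* direction by
default — tumor-bearing mice present hypothermia, not fever — with an
above-only switch for rubrics that define it that way.

## Group statistics

Mann–Whitney U, two-sided, exact null distribution when min(n) ≤ 8 and the
pooled sample is tie-free (covering group sizes 4–8 typical of these
designs), tie-corrected normal approximation otherwise. Kruskal–Wallis with
tie correction for ≥3 groups; its post hoc is pairwise Mann–Whitney under
Bonferroni over the number of pairs. Summaries are mean ± SEM (sample SD,
n−1, over √n); n = 1 reports SEM 0 with a warning. All tests are two-sided.

## Verification problem sizes

The test suite verifies, among others: time-domain metrics against a naive
double-loop reference on 1000 random series of length 2–2000 (1e−9 relative
tolerance); detector sensitivity/PPV ≥ 0.99 and timing MAE < 2 ms pooled over
twenty 5-minute 2 kHz recordings at 10 dB SNR; generator-parameter recovery
(mean RR within 2%, jitter SD within 15% over 20 recordings); band
specificity (>80% of in-band power in the modulated band) and Parseval
consistency (within 5% over 50 noise draws); cancer-like vs naive-like
direction of effect significant at p < 0.05 for all three time-domain metrics
in ≥95 of 100 replicate studies (means-as-settings mode, n = 5 vs 8); and
Mann–Whitney type-I error within [0.03, 0.07] over 2000 null simulations.
These sizes were chosen to give stable Monte-Carlo estimates at interactive
runtimes.

## Known limitations

* The detector is tuned for murine morphology; constants are exposed in
  `DetectorConfig` but defaults will mis-serve human or large-animal ECG.
* Artifact screening is rule-based and permissive; heavily corrupted
  telemetry needs upstream quality control.
* No nonlinear HRV indices (Poincaré SD1/SD2, entropies, DFA) — the linear
  time/frequency set only.
* File I/O covers the package's documented text formats only; vendor binary
  formats are out of scope.
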