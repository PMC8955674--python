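"""Synthetic mouse RR-interval series and ECG waveforms with known ground truth.

The beat-time model is an interval-sampling approximation of integral pulse
frequency modulation (IPFM): the instantaneous RR signal

    RR(t) = mean_rr + lf_amp * sin(2*pi*lf_freq*t) + hf_amp * sin(2*pi*hf_freq*t)

is evaluated at the previous beat time to give the next interval, plus white
Gaussian beat-to-beat jitter.  The scheme is exactly invertible (ground-truth
beat times and intervals are returned), and at the modulation depths used in
murine HRV the difference from threshold-crossing IPFM is negligible.

The ECG synthesizer places a 5-Gaussian PQRST template at every ground-truth
R time, then adds single-tone baseline wander and white Gaussian noise.
Component widths are full widths at half maximum (FWHM) in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError
from .rri_processing import RRISeries
from .signal_io import ECGRecord

#: Murine low-/high-frequency modulation bands (Hz): LF 0.1-1.0, HF 1.0-4.0.
LF_BAND = (0.1, 1.0)
HF_BAND = (1.0, 4.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class RRSynthConfig:
    """Parameters of the synthetic RR-interval process.

    Defaults describe a resting adult mouse: ~100 ms mean RR (600 bpm) with
    LF and HF sinusoidal modulation inside the murine bands and a few ms of
    white beat-to-beat jitter.
    """

    mean_rr: float = 100.0      # ms
    lf_amp: float = 2.0         # ms
    lf_freq: float = 0.4        # Hz, must lie in (0.1, 1.0)
    hf_amp: float = 3.0         # ms
    hf_freq: float = 2.5        # Hz, must lie in (1.0, 4.0)
    jitter_sd: float = 2.0      # ms
    duration: float = 300.0     # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ConfigurationError(f"mean_rr must be > 0, got {self.mean_rr}")
        if self.duration <= 0:
            raise ConfigurationError(f"duration must be > 0, got {self.duration}")
        if self.jitter_sd < 0:
            raise ConfigurationError(f"jitter_sd must be >= 0, got {self.jitter_sd}")
        if self.lf_amp < 0 or self.hf_amp < 0:
            raise ConfigurationError("modulation amplitudes must be >= 0")
        if self.lf_amp > 0 and not (LF_BAND[0] < self.lf_freq < LF_BAND[1]):
            raise ConfigurationError(
                f"lf_freq must lie in ({LF_BAND[0]}, {LF_BAND[1]}) Hz, got {self.lf_freq}"
            )
        if self.hf_amp > 0 and not (HF_BAND[0] < self.hf_freq < HF_BAND[1]):
            raise ConfigurationError(
                f"hf_freq must lie in ({HF_BAND[0]}, {HF_BAND[1]}) Hz, got {self.hf_freq}"
            )
        if self.lf_amp + self.hf_amp + 4.0 * self.jitter_sd >= self.mean_rr:
            raise ConfigurationError(
                "lf_amp + hf_amp + 4*jitter_sd must be < mean_rr "
                "to guarantee strictly positive intervals"
            )


#: Default mouse PQRST template: (amplitude mV, center offset ms, FWHM ms).
#: R is ~5 ms wide and 1 mV, dominating all other deflections; values chosen
#: so the QRS duration matches rodent physiology (~10 ms).
DEFAULT_TEMPLATE = (
    (0.10, -25.0, 10.0),   # P
    (-0.12, -8.0, 5.0),    # Q
    (1.00, 0.0, 5.0),      # R
    (-0.20, 8.0, 5.0),     # S
    (0.25, 25.0, 15.0),    # T
)


@dataclass(frozen=True)
class ECGSynthConfig:
    """Parameters of the waveform synthesizer.

    ``template_params`` lists Gaussian components as (amplitude mV, center
    offset ms relative to the R time, FWHM ms).  The R component (largest
    positive offset-0 deflection) must strictly dominate all others in
    absolute amplitude.  Default sampling rate is 2 kHz; higher rates
    (e.g. telemetry-grade 32 kHz) are supported directly.
    """

    sampling_rate: float = 2000.0
    template_params: tuple = DEFAULT_TEMPLATE
    noise_sd: float = 0.0               # mV
    baseline_wander_amp: float = 0.0    # mV
    baseline_wander_freq: float = 0.3   # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not self.template_params:
            raise ConfigurationError("template_params must list at least one component")
        amps = [abs(a) for a, _, _ in self.template_params]
        widths = [w for _, _, w in self.template_params]
        if any(w <= 0 for w in widths):
            raise ConfigurationError("template component widths must be > 0")
        r_amp = abs(self.r_component[0])
        if sum(a >= r_amp for a in amps) > 1:
            raise ConfigurationError(
                "R component amplitude must strictly dominate all other components"
            )
        if self.noise_sd < 0 or self.baseline_wander_amp < 0:
            raise ConfigurationError("noise and wander amplitudes must be >= 0")

    @property
    def r_component(self) -> tuple:
        """The template component with the largest absolute amplitude."""
        return max(self.template_params, key=lambda c: abs(c[0]))


@dataclass
class GroundTruth:
    """What the generator actually produced, for scoring detectors.

    ``beat_times`` includes the beat opening the first interval, so
    ``len(true_rri) == len(beat_times) - 1``.  ``band_fractions`` gives the
    fraction of deterministic modulation variance per band (``lf``/``hf``).
    """

    beat_times: np.ndarray
    true_rri: np.ndarray
    band_fractions: dict = field(default_factory=dict)


def _instantaneous_rr(cfg: RRSynthConfig, t: np.ndarray | float):
    return (
        cfg.mean_rr
        + cfg.lf_amp * np.sin(2.0 * np.pi * cfg.lf_freq * t)
        + cfg.hf_amp * np.sin(2.0 * np.pi * cfg.hf_freq * t)
    )


def generate_rri(config: RRSynthConfig) -> tuple[RRISeries, GroundTruth]:
    """Generate a beat sequence spanning at least ``config.duration`` seconds.

    The i-th interval is RR evaluated at the (i-1)-th beat time plus
    independent N(0, jitter_sd^2) noise; the config invariant guarantees every
    interval stays strictly positive.
    """
    rng = np.random.default_rng(config.seed)
    times = [0.0]
    intervals: list[float] = []
    t = 0.0
    # small tolerance so accumulated float error cannot add a spurious beat
    stop = config.duration - 1e-9 * max(1.0, config.duration)
    while t < stop:
        rr = float(_instantaneous_rr(config, t))
        if config.jitter_sd > 0:
            # truncate at 4 sigma: keeps intervals positive per the invariant
            j = float(rng.normal(0.0, config.jitter_sd))
            j = max(-4.0 * config.jitter_sd, min(4.0 * config.jitter_sd, j))
            rr += j
        t += rr / 1000.0
        times.append(t)
        intervals.append(rr)
    beat_times = np.array(times)
    true_rri = np.array(intervals)
    lf_var = config.lf_amp**2 / 2.0
    hf_var = config.hf_amp**2 / 2.0
    tot = lf_var + hf_var
    fractions = {
        "lf": lf_var / tot if tot > 0 else 0.0,
        "hf": hf_var / tot if tot > 0 else 0.0,
    }
    series = RRISeries(intervals=true_rri, beat_times=beat_times[1:])
    truth = GroundTruth(beat_times=beat_times, true_rri=true_rri, band_fractions=fractions)
    return series, truth


def generate_ecg(
    rri: RRISeries, config: ECGSynthConfig = ECGSynthConfig()
) -> tuple[ECGRecord, GroundTruth]:
    """Render an ECG waveform for the given beat sequence.

    One PQRST template is centered at every R time (the beat times of ``rri``
    plus the beat opening its first interval).  An empty series yields a
    baseline-only record of zero beats.
    """
    fs = config.sampling_rate
    narrowest = min(w for _, _, w in config.template_params)
    if fs * narrowest / 1000.0 < 10.0:
        raise ConfigurationError(
            f"sampling_rate {fs} Hz gives fewer than 10 samples across the "
            f"narrowest template width ({narrowest} ms)"
        )
    # lead-in/out of baseline so the record does not start or end mid-QRS
    pad = 0.1
    if rri.n == 0:
        beat_times = np.array([])
        duration = 1.0
    else:
        beat_times = np.concatenate([[rri.start_time], rri.beat_times]) + pad
        duration = beat_times[-1] + pad
    n = int(round(duration * fs)) + 1
    tgrid = np.arange(n) / fs

    signal = np.zeros(n)
    # each component spans +-4 sigma around its center; add per beat on a slice
    for amp, offset_ms, width_ms in config.template_params:
        sigma = width_ms * _FWHM_TO_SIGMA / 1000.0
        half = 4.0 * sigma
        for bt in beat_times:
            c = bt + offset_ms / 1000.0
            i0 = max(0, int(math.ceil((c - half) * fs)))
            i1 = min(n, int(math.floor((c + half) * fs)) + 1)
            if i1 <= i0:
                continue
            tt = tgrid[i0:i1]
            signal[i0:i1] += amp * np.exp(-0.5 * ((tt - c) / sigma) ** 2)

    rng = np.random.default_rng(config.seed)
    if config.baseline_wander_amp > 0:
        signal += config.baseline_wander_amp * np.sin(
            2.0 * np.pi * config.baseline_wander_freq * tgrid
        )
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=n)

    # snap truth to the sample grid: R centers are within half a sample
    truth_times = np.round(beat_times * fs) / fs
    record = ECGRecord(samples=signal, sampling_rate=fs)
    truth = GroundTruth(
        beat_times=truth_times,
        true_rri=np.diff(truth_times) * 1000.0 if truth_times.size else np.array([]),
        band_fractions={},
    )
    return record, truth


def jitter_for_rmssd(
    target_rmssd: float,
    mean_rr: float,
    lf_amp: float = 0.0,
    lf_freq: float = 0.4,
    hf_amp: float = 0.0,
    hf_freq: float = 2.5,
) -> float:
    """Jitter SD (ms) so the generated series has the requested RMSSD.

    For a sinusoid of amplitude a sampled every T = mean_rr seconds the
    expected squared successive difference is 2 a^2 sin^2(pi f T); white
    jitter adds 2 sigma^2.  Solving RMSSD^2 = 2 sigma^2 + sum of modulation
    terms gives sigma.  Raises if the modulation alone already exceeds the
    target.
    """
    T = mean_rr / 1000.0
    mod = 2.0 * lf_amp**2 * math.sin(math.pi * lf_freq * T) ** 2
    mod += 2.0 * hf_amp**2 * math.sin(math.pi * hf_freq * T) ** 2
    resid = target_rmssd**2 - mod
    if -1e-9 * max(1.0, mod) <= resid < 0:  # rounding at the exact floor
        resid = 0.0
    if resid < 0:
        raise ConfigurationError(
            f"modulation alone yields RMSSD {math.sqrt(mod):.3f} ms, above the "
            f"target {target_rmssd} ms"
        )
    return math.sqrt(resid / 2.0)


# ---------------------------------------------------------------------------
# Cohort profiles
# ---------------------------------------------------------------------------
# Day-12 group conditions of the peritoneal-metastasis pain study the package
# models: a healthy ("naive-like") cohort with long RR intervals and strong
# beat-to-beat variability versus a tumor-burdened ("cancer-like") cohort with
# shortened intervals and collapsed vagal modulation.  Group-level means and
# between-subject SDs follow the study-scale values (mean +- SEM converted to
# SD via SEM * sqrt(n)).

NAIVE_PROFILE = {
    "mean_rr": 135.8685, "mean_rr_sd": 16.357,   # SEM 7.3151, n=5
    "rmssd": 11.1277, "rmssd_sd": 4.671,         # SEM 2.0890, n=5
    "lf_amp": 2.0, "hf_amp": 3.0,
}
CANCER_PROFILE = {
    "mean_rr": 98.6941, "mean_rr_sd": 10.778,    # SEM 3.8106, n=8
    "rmssd": 3.5971, "rmssd_sd": 2.020,          # SEM 0.7143, n=8
    "lf_amp": 0.5, "hf_amp": 1.0,
}

#: Loading of the shared latent "autonomic severity" factor on a subject's
#: mean-RR and RMSSD perturbations: vagal withdrawal shortens intervals and
#: suppresses variability together, so the two are positively correlated.
SEVERITY_LOADING = 0.7


def profile_config(
    profile: dict,
    duration: float = 300.0,
    seed: int = 0,
    lf_freq: float = 0.4,
    hf_freq: float = 2.5,
) -> RRSynthConfig:
    """Generator config at exactly the profile means (no subject-level draw).

    The jitter SD is solved so the generated series has the profile's RMSSD
    via :func:`jitter_for_rmssd`.
    """
    jitter = jitter_for_rmssd(
        profile["rmssd"], profile["mean_rr"],
        profile["lf_amp"], lf_freq, profile["hf_amp"], hf_freq,
    )
    return RRSynthConfig(
        mean_rr=profile["mean_rr"],
        lf_amp=profile["lf_amp"], lf_freq=lf_freq,
        hf_amp=profile["hf_amp"], hf_freq=hf_freq,
        jitter_sd=jitter, duration=duration, seed=seed,
    )


def cohort_configs(
    profile: dict,
    n_subjects: int,
    duration: float = 300.0,
    seed: int = 0,
    lf_freq: float = 0.4,
    hf_freq: float = 2.5,
    subject_variation: bool = True,
) -> list[RRSynthConfig]:
    """Per-subject generator configs for a cohort.

    With ``subject_variation`` (default) subject-level mean RR and RMSSD are
    Gaussian around the profile means with the profile SDs; their
    perturbations share a latent severity factor with loading
    :data:`SEVERITY_LOADING`.  RMSSD draws are floored at 0.5 ms and at the
    deterministic-modulation floor, and the jitter SD is solved from the
    subject's RMSSD target via :func:`jitter_for_rmssd`.

    Without it, every subject uses exactly the profile means and differs
    only in the random seed — the configuration for qualitative
    direction-of-effect checks, where the group means themselves are the
    generator settings.
    """
    rng = np.random.default_rng(seed)
    if not subject_variation:
        return [
            profile_config(
                profile, duration=duration,
                seed=int(rng.integers(0, 2**31 - 1)),
                lf_freq=lf_freq, hf_freq=hf_freq,
            )
            for _ in range(n_subjects)
        ]
    load = SEVERITY_LOADING
    resid = math.sqrt(1.0 - load**2)
    configs = []
    for i in range(n_subjects):
        z = rng.normal()
        # clip at 3 sigma so extreme draws cannot break the positivity invariant
        z_rr = float(np.clip(load * z + resid * rng.normal(), -3.0, 3.0))
        z_var = float(np.clip(load * z + resid * rng.normal(), -3.0, 3.0))
        mean_rr = profile["mean_rr"] + profile["mean_rr_sd"] * z_rr
        rmssd = max(0.5, profile["rmssd"] + profile["rmssd_sd"] * z_var)
        # the deterministic modulation sets a floor on achievable RMSSD
        mod_rmssd = math.sqrt(
            2.0 * profile["lf_amp"] ** 2 * math.sin(math.pi * lf_freq * mean_rr / 1000.0) ** 2
            + 2.0 * profile["hf_amp"] ** 2 * math.sin(math.pi * hf_freq * mean_rr / 1000.0) ** 2
        )
        rmssd = max(rmssd, mod_rmssd)
        jitter = jitter_for_rmssd(
            rmssd, mean_rr, profile["lf_amp"], lf_freq, profile["hf_amp"], hf_freq
        )
        configs.append(
            RRSynthConfig(
                mean_rr=mean_rr,
                lf_amp=profile["lf_amp"], lf_freq=lf_freq,
                hf_amp=profile["hf_amp"], hf_freq=hf_freq,
                jitter_sd=jitter,
                duration=duration,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return configs
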