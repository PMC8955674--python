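"""Frequency-domain HRV: tachogram, Welch spectrum, and murine band powers.

The RR-interval series is resampled onto a uniform 10 Hz grid with a natural
cubic spline (the tachogram), its one-sided power spectral density is
estimated by Welch's averaged-periodogram method, and band powers are
trapezoidal integrals of the PSD over the murine low-frequency (0.1-1.0 Hz)
and high-frequency (1.0-4.0 Hz) bands.  HF indexes parasympathetic tone, LF
mixes both autonomic branches, and LF/HF indexes sympathovagal balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .exceptions import ConfigurationError, InsufficientDataError
from .rri_processing import RRISeries

#: Tachogram resampling rate (Hz).
TACHOGRAM_RATE = 10.0


@dataclass(frozen=True)
class BandSpec:
    """LF/HF band edges in Hz; the shared 1.0 Hz edge belongs to HF."""

    lf: tuple[float, float] = (0.1, 1.0)
    hf: tuple[float, float] = (1.0, 4.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("lf", self.lf), ("hf", self.hf)):
            if not (0 < lo < hi):
                raise ConfigurationError(f"{name} band must satisfy 0 < lo < hi, got {lo}-{hi}")
        if self.lf[1] > self.hf[0]:
            raise ConfigurationError("LF and HF bands may share at most an endpoint")

    @property
    def total(self) -> tuple[float, float]:
        """Union of the defined bands, used for total power."""
        return (self.lf[0], self.hf[1])


@dataclass(frozen=True)
class WelchConfig:
    """Welch estimator settings.

    512 samples per segment at 10 Hz gives ~0.02 Hz resolution, enough to
    resolve the 0.1 Hz LF edge; Hann window, 50% overlap, mean detrend.
    """

    segment_length: int = 512
    overlap_frac: float = 0.5
    window_fn: str = "hann"
    detrend: str = "mean"  # one of mean, linear, none

    def __post_init__(self) -> None:
        if self.segment_length < 8:
            raise ConfigurationError("segment_length must be >= 8 samples")
        if not (0 <= self.overlap_frac < 1):
            raise ConfigurationError("overlap_frac must lie in [0, 1)")
        if self.detrend not in ("mean", "linear", "none"):
            raise ConfigurationError(f"unknown detrend {self.detrend!r}")


@dataclass
class Tachogram:
    """Uniformly resampled RR-interval signal (ms at ``sampling_rate`` Hz)."""

    values: np.ndarray
    sampling_rate: float = TACHOGRAM_RATE
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate <= 0:
            raise ConfigurationError("tachogram sampling_rate must be > 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SpectralEstimate:
    """One-sided PSD in ms^2/Hz on a monotone frequency grid."""

    frequencies: np.ndarray
    psd: np.ndarray
    segment_count: int = 1


@dataclass(frozen=True)
class FreqDomainHRV:
    lf_power: float     # ms^2
    hf_power: float     # ms^2
    lf_hf: float        # dimensionless; nan when hf_power == 0
    total_power: float  # ms^2 over the union of bands


def build_tachogram(series: RRISeries, rate: float = TACHOGRAM_RATE) -> Tachogram:
    """Natural cubic spline through (beat time, interval) knots on a uniform grid.

    Only retained intervals serve as knots.  The grid starts at the first
    knot and never extrapolates beyond the last.
    """
    mask = series.retained_mask
    t = series.beat_times[mask]
    v = series.intervals[mask]
    if v.size < 4:
        raise InsufficientDataError(
            f"cubic-spline tachogram needs >= 4 retained intervals, got {v.size}"
        )
    spline = CubicSpline(t, v, bc_type="natural")
    n = int(math.floor((t[-1] - t[0]) * rate)) + 1
    grid = t[0] + np.arange(n) / rate
    return Tachogram(values=spline(grid), sampling_rate=rate, start_time=float(t[0]))


def welch_psd(tachogram: Tachogram, config: WelchConfig = WelchConfig()) -> SpectralEstimate:
    """Welch PSD of the tachogram, normalized so the spectral integral over
    [0, Nyquist] matches the variance of the detrended signal."""
    n = len(tachogram)
    if n < config.segment_length:
        raise InsufficientDataError(
            f"tachogram of {n} samples is shorter than the "
            f"{config.segment_length}-sample Welch segment"
        )
    detrend = {"mean": "constant", "linear": "linear", "none": False}[config.detrend]
    noverlap = int(config.segment_length * config.overlap_frac)
    freqs, psd = sps.welch(
        tachogram.values,
        fs=tachogram.sampling_rate,
        window=config.window_fn,
        nperseg=config.segment_length,
        noverlap=noverlap,
        detrend=detrend,
        scaling="density",
    )
    step = config.segment_length - noverlap
    segments = max(1, 1 + (n - config.segment_length) // step)
    return SpectralEstimate(frequencies=freqs, psd=psd, segment_count=int(segments))


def band_power(spec: SpectralEstimate, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over [f_lo, f_hi] (ms^2).

    Bins straddling a band edge contribute pro-rata: the PSD is linearly
    interpolated at the exact edges before integrating.
    """
    f_lo, f_hi = band
    if f_lo >= f_hi:
        raise ConfigurationError(f"inverted band [{f_lo}, {f_hi}]")
    f = np.asarray(spec.frequencies)
    p = np.asarray(spec.psd)
    inner = (f > f_lo) & (f < f_hi)
    fs = np.concatenate([[f_lo], f[inner], [f_hi]])
    ps = np.concatenate([
        [np.interp(f_lo, f, p)], p[inner], [np.interp(f_hi, f, p)]
    ])
    return float(np.trapezoid(ps, fs))


def freq_metrics(
    series: RRISeries,
    bands: BandSpec = BandSpec(),
    welch: WelchConfig = WelchConfig(),
    rate: float = TACHOGRAM_RATE,
) -> FreqDomainHRV:
    """Tachogram -> Welch -> band powers for one analysis window."""
    spec = welch_psd(build_tachogram(series, rate=rate), welch)
    lf = band_power(spec, bands.lf)
    hf = band_power(spec, bands.hf)
    total = band_power(spec, bands.total)
    ratio = lf / hf if hf > 0 else float("nan")
    return FreqDomainHRV(lf_power=lf, hf_power=hf, lf_hf=ratio, total_power=total)
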