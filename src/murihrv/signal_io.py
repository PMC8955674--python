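"""Delimited-text I/O for ECG records, RR-interval series and result tables.

Native format: UTF-8 text, ``#`` comment lines, a header of ``key=value``
lines, then one sample (or one interval) per line.  Times are seconds,
intervals milliseconds, voltages millivolts throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: Closed set of group labels used in study tables.
GROUP_LABELS = ("naive", "cancer", "cancer_saline", "cancer_tramadol")

#: Fixed column order of the results CSV.
RESULT_COLUMNS = ("subject_id", "group", "timepoint", "metric", "value")


@dataclass
class ECGRecord:
    """Single-channel ECG voltage trace with acquisition metadata.

    Parameters
    ----------
    samples
        Voltage samples in mV; must be finite.
    sampling_rate
        Sampling rate in Hz; must be > 0.
    subject_id, timepoint, channel
        Free-text labels carried through the pipeline.
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = ""
    timepoint: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValidationError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return len(self.samples) / self.sampling_rate

    def __len__(self) -> int:
        return len(self.samples)


def _parse_header_and_values(path: Path, n_columns: int) -> tuple[dict, list, int]:
    """Read '#'-comment / 'key=value' header lines then numeric data lines.

    Returns (header dict, list of per-line float tuples, line number of first
    data line) and raises :class:`FormatError` with a line number on bad data.
    """
    header: dict[str, str] = {}
    values: list[tuple[float, ...]] = []
    lineno = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" in line and not values:
                key, _, val = line.partition("=")
                header[key.strip()] = val.strip()
                continue
            parts = line.split()
            if len(parts) != n_columns:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_columns} column(s), got {len(parts)}"
                )
            try:
                values.append(tuple(float(p) for p in parts))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value {line!r}") from None
    return header, values, lineno if values else 0


def read_ecg(path, format_spec: dict | None = None) -> ECGRecord:
    """Read an ECG record from the native one-sample-per-line text format.

    The header must declare ``sampling_rate_hz``; ``subject_id``,
    ``timepoint`` and ``channel`` are optional.  ``format_spec`` may override
    the header key used for the sampling rate (``rate_key``).
    """
    path = Path(path)
    rate_key = (format_spec or {}).get("rate_key", "sampling_rate_hz")
    header, values, _ = _parse_header_and_values(path, n_columns=1)
    if rate_key not in header:
        raise FormatError(f"{path}: header missing required key {rate_key!r}")
    try:
        rate = float(header[rate_key])
    except ValueError:
        raise FormatError(f"{path}: non-numeric sampling rate {header[rate_key]!r}") from None
    if rate <= 0:
        raise FormatError(f"{path}: sampling rate must be > 0, got {rate}")
    samples = np.array([v[0] for v in values], dtype=float)
    return ECGRecord(
        samples=samples,
        sampling_rate=rate,
        subject_id=header.get("subject_id", ""),
        timepoint=header.get("timepoint", ""),
        channel=header.get("channel", ""),
    )


def write_ecg(record: ECGRecord, path) -> None:
    """Write an ECG record in the native text format (9 significant digits)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# murihrv ecg v1\n")
        fh.write(f"sampling_rate_hz={record.sampling_rate:.9g}\n")
        for key in ("subject_id", "timepoint", "channel"):
            val = getattr(record, key)
            if val:
                fh.write(f"{key}={val}\n")
        for v in record.samples:
            fh.write(f"{v:.9g}\n")


def read_rri(path):
    """Read an RR-interval series: lines of ``interval_ms  beat_time_s``.

    Returns
    -------
    RRISeries
        With the beat-time convention used everywhere in the package (the
        time of the beat *ending* each interval).
    """
    from .rri_processing import RRISeries  # local import avoids cycle

    path = Path(path)
    header, values, _ = _parse_header_and_values(path, n_columns=2)
    intervals = np.array([v[0] for v in values])
    times = np.array([v[1] for v in values])
    if np.any(intervals <= 0):
        bad = float(intervals[intervals <= 0][0])
        raise ValidationError(f"{path}: non-positive RR interval {bad} ms")
    return RRISeries(intervals=intervals, beat_times=times)


def write_rri(series, path) -> None:
    """Write an RR-interval series (interval ms, cumulative beat time s)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# murihrv rri v1\n")
        fh.write("# interval_ms beat_time_s\n")
        for rri, t in zip(series.intervals, series.beat_times):
            fh.write(f"{rri:.9g} {t:.9g}\n")


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column order, closed group labels, and key uniqueness."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"study table missing columns {missing}")
    bad = set(table["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValidationError(f"unknown group label(s) {sorted(bad)}; allowed: {GROUP_LABELS}")
    keys = table[["subject_id", "timepoint", "metric"]]
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0].tolist()
        raise ValidationError(f"duplicate (subject, timepoint, metric) key {dup}")
    return table[list(RESULT_COLUMNS)]


def write_results(table: pd.DataFrame, path) -> None:
    """Write a validated study table as CSV with the fixed column order."""
    validate_study_table(table).to_csv(path, index=False)


def read_results(path) -> pd.DataFrame:
    """Read a results CSV back into a validated study table."""
    return validate_study_table(pd.read_csv(path))
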