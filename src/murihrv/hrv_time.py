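"""Time-domain HRV metrics over a windowed, screened RR-interval series.

* mean RRI — arithmetic mean of the retained intervals (ms);
* RMSSD — sqrt( sum (RR_{i+1} - RR_i)^2 / n_pairs ) over valid adjacent
  retained pairs (ms), a parasympathetic-activity index;
* pNN5 — percentage of valid pairs whose successive difference exceeds 5 ms
  (strict inequality), the rodent analogue of human pNN50.  Absolute
  differences by default; a signed variant is available because either
  reading of the defining expression is found in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InsufficientDataError
from .rri_processing import RRISeries

#: Successive-difference threshold (ms) defining pNN5.
PNN_THRESHOLD_MS = 5.0


@dataclass(frozen=True)
class TimeDomainHRV:
    mean_rri: float     # ms
    rmssd: float        # ms
    pnn5: float         # %
    n_intervals: int
    n_pairs: int


def mean_rri(series: RRISeries) -> float:
    """Arithmetic mean (ms) of the retained intervals."""
    vals = series.retained
    if vals.size == 0:
        raise InsufficientDataError("mean RRI needs at least one retained interval")
    return float(np.mean(vals))


def rmssd(series: RRISeries) -> float:
    """Root mean square of successive differences (ms) over valid pairs."""
    diffs = series.valid_pairs()
    if diffs.size == 0:
        raise InsufficientDataError("RMSSD needs at least one valid adjacent pair")
    return float(np.sqrt(np.mean(diffs**2)))


def pnn5(series: RRISeries, threshold: float = PNN_THRESHOLD_MS, signed: bool = False) -> float:
    """Percentage of successive differences strictly greater than 5 ms.

    ``signed=True`` counts only positive differences above the threshold
    instead of absolute differences.
    """
    diffs = series.valid_pairs()
    if diffs.size == 0:
        raise InsufficientDataError("pNN5 needs at least one valid adjacent pair")
    compared = diffs if signed else np.abs(diffs)
    return float(100.0 * np.count_nonzero(compared > threshold) / diffs.size)


def time_domain_metrics(series: RRISeries, signed_pnn: bool = False) -> TimeDomainHRV:
    """Bundle the three time-domain metrics for one analysis window."""
    diffs = series.valid_pairs()
    return TimeDomainHRV(
        mean_rri=mean_rri(series),
        rmssd=rmssd(series),
        pnn5=pnn5(series, signed=signed_pnn),
        n_intervals=int(series.retained.size),
        n_pairs=int(diffs.size),
    )
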