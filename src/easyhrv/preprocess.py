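"""Adaptive artifact filtering of beat series.

Beat detectors produce two kinds of errors: false detections (an artifact
mistaken for a beat, yielding a spuriously short RR interval) and missed
detections (a real beat not detected, merging two intervals into one long
one).  Ventricular ectopic beats are likewise unusable for variability
analysis.  The filter removes interval values inconsistent with
physiological heart-rate ranges or with their local context.

Acceptance rule (per beat, on the instantaneous heart rate):

* hard range: the rate must lie in ``[min_bpm, max_bpm]``;
* adaptive: the rate must be within ``last_tolerance`` percent of the
  previously accepted beat's rate, or of the next beat's rate, or within
  ``mean_tolerance`` percent of the running mean rate of the last
  ``long_window`` accepted beats.

Rejected beats have their RR *values* removed from the series; surviving
beats keep their original RR values and the output beat times are rebuilt
from the surviving intervals, so the output is again a consistent
:class:`~easyhrv.series.BeatSeries` and the filter is idempotent.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import BeatSeries

__all__ = ["FilterParams", "RemovalLog", "filter_beats"]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the adaptive beat filter.

    Defaults mirror the documented conventions of the reference HRV
    ecosystem: a 50-beat running mean, 13% beat-to-beat tolerance, 20%
    tolerance around the running mean, and a 25-200 bpm hard range.
    """

    long_window: int = 50
    last_tolerance: float = 13.0
    mean_tolerance: float = 20.0
    min_bpm: float = 25.0
    max_bpm: float = 200.0

    def __post_init__(self) -> None:
        if not (0 < self.last_tolerance < 100 and 0 < self.mean_tolerance < 100):
            raise ValueError("tolerances must lie in (0, 100)")
        if not self.min_bpm < self.max_bpm:
            raise ValueError("min_bpm must be below max_bpm")
        if self.long_window < 1:
            raise ValueError("long_window must be >= 1")


@dataclass
class RemovalLog:
    """Per-beat rejection records: index, time and reason."""

    entries: list[dict] = field(default_factory=list)

    def add(self, beat_index: int, time_s: float, reason: str) -> None:
        self.entries.append(
            {"beat_index": beat_index, "time_s": time_s, "reason": reason}
        )

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self, recording_id: str = "") -> pd.DataFrame:
        """Export as a CSV-ready table."""
        df = pd.DataFrame(
            self.entries, columns=["beat_index", "time_s", "reason"]
        )
        df.insert(0, "recording_id", recording_id)
        return df


def _within(value: float, ref: float, pct: float) -> bool:
    return abs(value - ref) <= (pct / 100.0) * ref


def filter_beats(
    series: BeatSeries, params: FilterParams | None = None
) -> tuple[BeatSeries, RemovalLog]:
    """Apply the adaptive filter; return the cleaned series and a log.

    Raises ``ValueError`` if no beats survive.
    """
    params = params or FilterParams()
    hr = series.nihr
    rr = series.rr
    times = series.beat_times[1:]  # beat ending each interval
    n = hr.size

    log = RemovalLog()
    kept = np.zeros(n, dtype=bool)
    recent: deque[float] = deque(maxlen=params.long_window)
    last_hr: float | None = None

    for i in range(n):
        h = hr[i]
        if not (params.min_bpm <= h <= params.max_bpm):
            log.add(i, float(times[i]), "range")
            continue
        ok = last_hr is None
        if not ok and _within(h, last_hr, params.last_tolerance):
            ok = True
        # the next-beat comparison counts only if that beat is itself
        # plausible (in range and near the running mean), so two adjacent
        # outliers cannot validate each other
        if (
            not ok
            and i + 1 < n
            and params.min_bpm <= hr[i + 1] <= params.max_bpm
            and (
                not recent
                or _within(hr[i + 1], float(np.mean(recent)), params.mean_tolerance)
            )
            and _within(h, hr[i + 1], params.last_tolerance)
        ):
            ok = True
        if not ok and recent and _within(
            h, float(np.mean(recent)), params.mean_tolerance
        ):
            ok = True
        if ok:
            kept[i] = True
            last_hr = h
            recent.append(h)
        else:
            log.add(i, float(times[i]), "adaptive")

    if not kept.any():
        raise ValueError("no beats survive filtering")
    return BeatSeries.from_rr(rr[kept]), log
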