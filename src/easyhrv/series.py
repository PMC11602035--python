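"""Beat series container.

A recording is represented by its beat occurrence times (seconds, first
beat at 0) together with the derived interbeat (RR) intervals in
milliseconds and the non-interpolated instantaneous heart rate (niHR) in
beats/min.  The three views are kept consistent: ``rr[i]`` is the interval
ending at ``beat_times[i + 1]`` and ``nihr[i] = 60000 / rr[i]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class BeatSeries:
    """Beat times plus derived RR intervals for a single recording.

    Parameters
    ----------
    beat_times : np.ndarray
        Beat occurrence times in seconds; strictly increasing, first 0.
    """

    beat_times: np.ndarray
    rr: np.ndarray = field(init=False, repr=False)
    nihr: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("a beat series needs at least two beats")
        if abs(t[0]) > 1e-12:
            t = t - t[0]
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise ValueError(
                f"non-positive interbeat interval at index {bad} "
                f"(dt={dt[bad]:.6g} s)"
            )
        object.__setattr__(self, "beat_times", t)
        object.__setattr__(self, "rr", 1000.0 * dt)
        object.__setattr__(self, "nihr", 60000.0 / (1000.0 * dt))

    @classmethod
    def from_rr(cls, rr_ms: np.ndarray) -> "BeatSeries":
        """Build a series from RR intervals in milliseconds.

        The first interval is taken to precede the first counted beat, so a
        series of n intervals has n + 1 beat times starting at 0.
        """
        rr_ms = np.asarray(rr_ms, dtype=float)
        if rr_ms.ndim != 1 or rr_ms.size < 1:
            raise ValueError("need at least one RR interval")
        if np.any(rr_ms <= 0):
            bad = int(np.argmax(rr_ms <= 0))
            raise ValueError(f"non-positive RR interval at index {bad}")
        t = np.concatenate([[0.0], np.cumsum(rr_ms) / 1000.0])
        series = cls(t)
        # keep the supplied intervals bit-exact (cumsum/diff round-trips
        # would perturb them at the ulp level)
        object.__setattr__(series, "rr", rr_ms.copy())
        object.__setattr__(series, "nihr", 60000.0 / rr_ms)
        return series

    @property
    def duration_s(self) -> float:
        return float(self.beat_times[-1])

    @property
    def n_beats(self) -> int:
        return int(self.beat_times.size)

    def __len__(self) -> int:
        return self.n_beats
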