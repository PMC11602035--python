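"""Time-domain HRV indices.

Ten indices computed from the RR interval sequence:

========  ==============================================================
SDNN      sample SD of all RR intervals (ms)
SDANN     SD over fixed windows of the per-window mean RR (ms)
SDNNIDX   mean over fixed windows of the per-window RR SD (ms)
pNN50     percent of successive differences exceeding 50 ms
SDSD      sample SD of successive differences (ms)
rMSSD     root mean square of successive differences (ms)
IRRR      interquartile range of RR (ms)
MADRR     median absolute successive difference (ms)
TINN      baseline width of the triangular histogram fit (ms)
HRVi      total interval count / modal histogram bin count
========  ==============================================================

SDANN and SDNNIDX use consecutive windows of ``window_s`` seconds
(default 300 s) anchored at the first beat.  If the recording spans only
one window, or any window contains no beats, both are set to NaN and a
warning is emitted; the statistics stage excludes NaN automatically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .series import BeatSeries

__all__ = ["TimeIndices", "compute_time_indices", "TIME_INDEX_NAMES"]

TIME_INDEX_NAMES = (
    "SDNN", "SDANN", "SDNNIDX", "pNN50", "SDSD",
    "rMSSD", "IRRR", "MADRR", "TINN", "HRVi",
)

#: Task-Force-standard RR histogram bin: 1/128 s in ms.
DEFAULT_BIN_WIDTH_MS = 1000.0 / 128.0


@dataclass(frozen=True)
class TimeIndices:
    SDNN: float
    SDANN: float
    SDNNIDX: float
    pNN50: float
    SDSD: float
    rMSSD: float
    IRRR: float
    MADRR: float
    TINN: float
    HRVi: float
    window_s: float = 300.0
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TIME_INDEX_NAMES}


def _triangular_fit(counts: np.ndarray, edges: np.ndarray) -> tuple[float, float]:
    """Least-squares triangular interpolation of the RR histogram.

    Searches bin edges N (below the mode) and M (above) for the triangle
    that rises linearly from 0 at N to the modal count at the mode and
    falls back to 0 at M, minimising the squared error against the
    histogram.  Returns (TINN, HRVi).
    """
    total = counts.sum()
    peak = int(np.argmax(counts))
    peak_count = counts[peak]
    hrvi = float(total / peak_count)
    centers = 0.5 * (edges[:-1] + edges[1:])
    x_peak = centers[peak]

    # Ascending side: choose edge n <= peak minimising sum of squared
    # residuals of counts vs the line 0 at edges[n] -> peak_count at x_peak.
    def side_error(candidates: np.ndarray, side: str) -> np.ndarray:
        errs = np.empty(candidates.size)
        for k, e in enumerate(candidates):
            if side == "left":
                idx = np.arange(0, peak)
                with np.errstate(divide="ignore", invalid="ignore"):
                    pred = peak_count * (centers[idx] - e) / (x_peak - e)
                pred = np.clip(pred, 0.0, None)
                pred[centers[idx] <= e] = 0.0
            else:
                idx = np.arange(peak + 1, counts.size)
                with np.errstate(divide="ignore", invalid="ignore"):
                    pred = peak_count * (e - centers[idx]) / (e - x_peak)
                pred = np.clip(pred, 0.0, None)
                pred[centers[idx] >= e] = 0.0
            errs[k] = np.sum((counts[idx] - pred) ** 2)
        return errs

    left_candidates = edges[: peak + 1]
    right_candidates = edges[peak + 1:]
    n_edge = left_candidates[int(np.argmin(side_error(left_candidates, "left")))]
    m_edge = right_candidates[int(np.argmin(side_error(right_candidates, "right")))]
    return float(m_edge - n_edge), hrvi


def compute_time_indices(
    series: BeatSeries,
    window_s: float = 300.0,
    bin_width_ms: float = DEFAULT_BIN_WIDTH_MS,
) -> TimeIndices:
    """Compute the ten time-domain indices for one recording."""
    rr = series.rr
    if rr.size < 2:
        raise ValueError("need at least two RR intervals")
    d = np.diff(rr)

    sdnn = float(np.std(rr, ddof=1))
    sdsd = float(np.std(d, ddof=1))
    rmssd = float(np.sqrt(np.mean(d**2)))
    pnn50 = float(100.0 * np.mean(np.abs(d) > 50.0))
    madrr = float(np.median(np.abs(d)))
    q1, q3 = np.percentile(rr, [25.0, 75.0])
    irrr = float(q3 - q1)

    # Histogram bins aligned to multiples of the bin width.
    lo = np.floor(rr.min() / bin_width_ms) * bin_width_ms
    hi = np.ceil(rr.max() / bin_width_ms) * bin_width_ms
    if hi <= lo:
        hi = lo + bin_width_ms
    edges = np.arange(lo, hi + 0.5 * bin_width_ms, bin_width_ms)
    counts, _ = np.histogram(rr, bins=edges)
    tinn, hrvi = _triangular_fit(counts.astype(float), edges)

    sdann, sdnnidx = _windowed_indices(series, window_s)

    return TimeIndices(
        SDNN=sdnn, SDANN=sdann, SDNNIDX=sdnnidx, pNN50=pnn50, SDSD=sdsd,
        rMSSD=rmssd, IRRR=irrr, MADRR=madrr, TINN=tinn, HRVi=hrvi,
        window_s=window_s, bin_width_ms=bin_width_ms,
    )


def _windowed_indices(series: BeatSeries, window_s: float) -> tuple[float, float]:
    rr = series.rr
    # interval assigned to the window containing its ending beat, relative
    # to the first beat; trailing partial window kept if it holds beats.
    t_end = series.beat_times[1:] - series.beat_times[0]
    win = np.floor(t_end / window_s).astype(int)
    n_windows = int(win.max()) + 1 if win.size else 0

    if n_windows <= 1:
        warnings.warn(
            "recording spans a single window; SDANN and SDNNIDX set to NA"
        )
        return np.nan, np.nan

    means, sds = [], []
    for w in range(n_windows):
        chunk = rr[win == w]
        if chunk.size == 0:
            warnings.warn(
                f"window {w} contains no beats; SDANN and SDNNIDX set to NA"
            )
            return np.nan, np.nan
        means.append(chunk.mean())
        sds.append(np.std(chunk, ddof=1) if chunk.size > 1 else 0.0)
    return float(np.std(means, ddof=1)), float(np.mean(sds))
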