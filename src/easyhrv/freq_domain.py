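"""Frequency-domain HRV indices.

The irregularly sampled instantaneous heart rate is linearly interpolated
onto a uniform grid (4 Hz by default) and spectral power is integrated
over four bands appropriate to resting adult humans:

* ULF: (0, 0.03] Hz — circadian/thermoregulatory drifts
* VLF: (0.03, 0.05] Hz — renin-angiotensin and peripheral vasomotor tone
* LF:  (0.05, 0.15] Hz — baroreflex, mixed sympathetic/parasympathetic
* HF:  (0.15, 0.4] Hz — respiratory sinus arrhythmia (parasympathetic)

Two estimators are provided.  The Fourier route removes a linear trend,
computes the periodogram, and smooths it with a composed modified Daniell
kernel; band power is the sum of the smoothed density over in-band
frequencies.  The wavelet route decomposes the detrended signal into
uniform wavelet-packet subbands (Daubechies-4), assigns subbands to the
four bands, and reports the time-averaged energy per band.  Powers are in
(beats/min)^2; band edges are half-open (lo, hi] so shared edges are
never double counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt

from .series import BeatSeries

__all__ = [
    "SpectralParams",
    "BandPowers",
    "interpolate_hr",
    "fourier_band_powers",
    "wavelet_band_powers",
    "compute_freq_indices",
    "FREQ_INDEX_NAMES",
]

FREQ_INDEX_NAMES = ("ULF", "VLF", "LF", "HF")

DEFAULT_BANDS = {
    "ULF": (0.0, 0.03),
    "VLF": (0.03, 0.05),
    "LF": (0.05, 0.15),
    "HF": (0.15, 0.4),
}


@dataclass(frozen=True)
class SpectralParams:
    interp_hz: float = 4.0
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    method: str = "fourier"
    daniell_spans: tuple[int, int] = (5, 5)
    wavelet_name: str = "db4"
    band_tolerance: float = 0.01

    def __post_init__(self) -> None:
        edges = list(self.bands.values())
        for (lo, hi) in edges:
            if not lo < hi:
                raise ValueError("band edges must be increasing")
        for (_, hi_a), (lo_b, _) in zip(edges[:-1], edges[1:]):
            if lo_b < hi_a:
                raise ValueError("bands must be disjoint and increasing")
        if self.interp_hz <= 2 * max(hi for _, hi in edges):
            raise ValueError("interpolation rate must exceed twice the top band edge")


@dataclass(frozen=True)
class BandPowers:
    """Absolute power per band in (beats/min)^2."""

    ULF: float
    VLF: float
    LF: float
    HF: float

    @property
    def total(self) -> float:
        return self.ULF + self.VLF + self.LF + self.HF

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FREQ_INDEX_NAMES}

    def dominant(self) -> str:
        d = self.as_dict()
        return max(d, key=d.get)


def interpolate_hr(series: BeatSeries, interp_hz: float = 4.0) -> np.ndarray:
    """Linearly interpolate the niHR onto a uniform grid.

    Heart rate is defined at each beat (except the first); samples run
    from the first rate-bearing beat to the last beat.
    """
    if series.n_beats < 2:
        raise ValueError("need at least two beats to interpolate")
    t = series.beat_times[1:]
    hr = series.nihr
    span = t[-1] - t[0]
    if span < 2.0 / interp_hz:
        raise ValueError("recording too short to interpolate at this rate")
    n = int(np.floor(span * interp_hz)) + 1
    grid = t[0] + np.arange(n) / interp_hz
    return np.interp(grid, t, hr)


def _detrend(x: np.ndarray) -> np.ndarray:
    n = x.size
    t = np.arange(n, dtype=float)
    a, b = np.polyfit(t, x, 1)
    return x - (a * t + b)


def _modified_daniell_kernel(span: int) -> np.ndarray:
    """Modified Daniell smoother of half-width ``span`` (half end weights)."""
    k = np.ones(2 * span + 1)
    k[0] = k[-1] = 0.5
    return k / k.sum()


def _composed_kernel(spans: tuple[int, ...]) -> np.ndarray:
    kernel = np.array([1.0])
    for s in spans:
        kernel = np.convolve(kernel, _modified_daniell_kernel(s))
    return kernel


def raw_periodogram(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram normalised so ordinates sum to the variance.

    Returns (frequencies as fractions of the sampling rate, ordinates).
    The DC ordinate is excluded; with a zero-mean input the sum of
    ordinates equals the (population) variance exactly.
    """
    n = x.size
    spec = np.fft.rfft(x)
    p = (np.abs(spec) ** 2) / n**2
    # fold two-sided power into one side (all but DC and, for even n, Nyquist)
    p[1:] *= 2.0
    if n % 2 == 0:
        p[-1] /= 2.0
    freqs = np.fft.rfftfreq(n)
    return freqs[1:], p[1:]


def fourier_band_powers(
    hr_signal: np.ndarray, params: SpectralParams | None = None
) -> BandPowers:
    """Detrended, Daniell-smoothed periodogram power per band."""
    params = params or SpectralParams()
    x = np.asarray(hr_signal, dtype=float)
    if np.all(np.isnan(x)):
        raise ValueError("signal is all-NaN")
    lowest_edge = min(hi for _, hi in params.bands.values())
    if x.size < 2 * params.interp_hz / lowest_edge:
        warnings.warn("signal is short relative to the lowest band; estimates are unstable")
    x = _detrend(x)
    frac, p = raw_periodogram(x)
    kernel = _composed_kernel(params.daniell_spans)
    pad = kernel.size // 2
    if p.size > pad:
        # reflective padding keeps the kernel mass at 1 near the edges
        smoothed = np.convolve(np.pad(p, pad, mode="reflect"), kernel,
                               mode="valid")
    else:
        smoothed = p  # too short to smooth meaningfully
    freqs_hz = frac * params.interp_hz
    powers = {}
    for name, (lo, hi) in params.bands.items():
        mask = (freqs_hz > lo) & (freqs_hz <= hi)
        powers[name] = float(smoothed[mask].sum())
    return BandPowers(**{k: powers.get(k, 0.0) for k in FREQ_INDEX_NAMES})


def _packet_depth(params: SpectralParams) -> int:
    """Smallest wavelet-packet depth whose uniform subband edges match
    every configured band edge within ``band_tolerance``."""
    edges = sorted({e for lo_hi in params.bands.values() for e in lo_hi if e > 0})
    for depth in range(3, 13):
        width = params.interp_hz / 2.0 / 2.0**depth
        if all(
            abs(e / width - round(e / width)) * width <= params.band_tolerance
            for e in edges
        ):
            return depth
    bad = ", ".join(f"{e:g} Hz" for e in edges)
    raise ValueError(
        f"no wavelet-packet depth resolves band edges ({bad}) within "
        f"tolerance {params.band_tolerance} Hz at {params.interp_hz} Hz"
    )


def wavelet_band_powers(
    hr_signal: np.ndarray, params: SpectralParams | None = None
) -> BandPowers:
    """Time-averaged wavelet energy per band.

    The detrended signal is decomposed with a wavelet packet transform
    into 2**depth uniform subbands; each band collects the subbands whose
    frequency interval it covers, and the band power is the total squared
    coefficient mass divided by the signal length (the time average of
    the instantaneous band power, by Parseval's relation for orthogonal
    wavelets).
    """
    params = params or SpectralParams()
    x = np.asarray(hr_signal, dtype=float)
    if np.all(np.isnan(x)):
        raise ValueError("signal is all-NaN")
    x = _detrend(x)
    depth = _packet_depth(params)
    wp = pywt.WaveletPacket(x, params.wavelet_name, mode="periodization", maxlevel=depth)
    nodes = wp.get_level(depth, order="freq")
    width = params.interp_hz / 2.0 / 2.0**depth
    n = x.size
    powers = dict.fromkeys(FREQ_INDEX_NAMES, 0.0)
    # snap band edges to the (tolerance-verified) subband grid so the
    # bands partition the subbands without overlap
    snapped = {
        name: (round(lo / width) * width, round(hi / width) * width)
        for name, (lo, hi) in params.bands.items()
    }
    for k, node in enumerate(nodes):
        center = (k + 0.5) * width
        for name, (lo, hi) in snapped.items():
            if lo < center <= hi:
                powers[name] += float(np.sum(np.asarray(node.data) ** 2)) / n
                break
    return BandPowers(**powers)


def compute_freq_indices(
    series: BeatSeries, params: SpectralParams | None = None
) -> BandPowers:
    """Interpolate the heart rate and estimate band powers."""
    params = params or SpectralParams()
    hr = interpolate_hr(series, params.interp_hz)
    if params.method == "wavelet":
        return wavelet_band_powers(hr, params)
    if params.method == "fourier":
        return fourier_band_powers(hr, params)
    raise ValueError(f"unknown spectral method {params.method!r}")
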