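"""Synthetic RR-series generation with known ground truth.

Provides controlled stand-ins for real beat recordings: a heart-rate
trajectory is built from one of four dynamics and converted to beat
times by integrate-and-fire (the standard IPFM surrogate), so spectral
and variability ground truth is known by construction.

Dynamics
--------
``gaussian``
    Band-limited Gaussian rate fluctuations around the mean (white noise
    smoothed below the HF edge), plus optional sinusoidal modulation.
``sinusoidal``
    Pure sum of sinusoids at the requested modulation frequencies.
``henon``
    The Hénon map (a = 1.4, b = 0.3) x-coordinate mapped affinely into a
    physiological RR range — a low-dimensional chaotic beat series whose
    correlation dimension (~1.2) and Lyapunov exponent (~0.42/iter) are
    known from the literature.
``periodic``
    A strictly periodic RR pattern (sinusoid in the beat index).

Artifact injection (``corrupt``) inserts spurious beats by splitting a
random interval and deletes beats by merging adjacent intervals, and
returns a map of every change, so filter performance can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import write_rr_file
from .series import BeatSeries

__all__ = ["SyntheticSpec", "gen_rr", "corrupt", "gen_cohort"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for one recording."""

    duration_s: float = 600.0
    mean_hr: float = 75.0          # bpm
    sd_hr: float = 5.0             # bpm, gaussian dynamics
    modulation: tuple = ((0.1, 2.0), (0.25, 3.0))  # (Hz, bpm amplitude)
    dynamics: str = "gaussian"
    artifact_rate: float = 0.0
    deletion_rate: float = 0.0
    seed: int = 0
    henon_rr_scale: float = 40.0   # ms per unit of Hénon x
    periodic_beats: int = 40       # period of the periodic pattern, beats
    periodic_amp_ms: float = 30.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        for rate in (self.artifact_rate, self.deletion_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")


def _integrate_and_fire(hr_bpm: np.ndarray, fs: float) -> np.ndarray:
    """Beat times from an instantaneous-rate trajectory.

    The cumulative integral of the rate (beats/s) is inverted at integer
    beat counts; the first beat is placed at t = 0.
    """
    rate = hr_bpm / 60.0
    t = np.arange(hr_bpm.size) / fs
    # cumulative beats at grid times (trapezoid)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) / fs)])
    n_beats = int(np.floor(cum[-1]))
    if n_beats < 2:
        raise ValueError("trajectory too short to produce two beats")
    targets = np.arange(n_beats + 1, dtype=float)
    targets = targets[targets <= cum[-1]]
    beat_times = np.interp(targets, cum, t)
    return beat_times - beat_times[0]


def gen_rr(spec: SyntheticSpec) -> tuple[BeatSeries, dict]:
    """Generate a beat series plus a ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    truth: dict = {"dynamics": spec.dynamics, "seed": spec.seed}

    if spec.dynamics in ("gaussian", "sinusoidal"):
        fs = 8.0
        n = int(spec.duration_s * fs) + 1
        t = np.arange(n) / fs
        hr = np.full(n, spec.mean_hr)
        if spec.dynamics == "gaussian" and spec.sd_hr > 0:
            noise = rng.standard_normal(n)
            # band-limit below ~0.4 Hz so fluctuations are physiological
            noise = gaussian_filter1d(noise, sigma=fs / (2 * np.pi * 0.4))
            noise *= spec.sd_hr / max(noise.std(), 1e-12)
            hr = hr + noise
        phases = rng.uniform(0, 2 * np.pi, len(spec.modulation))
        for (freq, amp), phi in zip(spec.modulation, phases):
            hr = hr + amp * np.sin(2 * np.pi * freq * t + phi)
        if hr.min() <= 0 or hr.max() > 300:
            raise ValueError("parameters drive HR outside (0, 300] bpm")
        series = BeatSeries(_integrate_and_fire(hr, fs))
        truth["modulation"] = [list(m) for m in spec.modulation]
        truth["mean_hr"] = spec.mean_hr

    elif spec.dynamics == "henon":
        mean_rr = 60000.0 / spec.mean_hr
        n_beats = max(int(spec.duration_s / (mean_rr / 1000.0)), 3)
        # seed-dependent start inside the basin; transient discarded
        x, y = 0.1 + 0.05 * rng.uniform(-1, 1), 0.1 + 0.05 * rng.uniform(-1, 1)
        for _ in range(1000):
            x, y = 1.0 - 1.4 * x * x + y, 0.3 * x
        xs = np.empty(n_beats)
        for i in range(n_beats):
            x, y = 1.0 - 1.4 * x * x + y, 0.3 * x
            xs[i] = x
        rr = mean_rr + spec.henon_rr_scale * xs
        if np.any(rr <= 200.0):
            raise ValueError("Hénon scaling drives RR outside physiology")
        series = BeatSeries.from_rr(rr)
        truth.update(correlation_dim=1.22, lyapunov_per_beat=0.42)

    elif spec.dynamics == "periodic":
        mean_rr = 60000.0 / spec.mean_hr
        n_beats = max(int(spec.duration_s / (mean_rr / 1000.0)), 3)
        k = np.arange(n_beats)
        theta = 2 * np.pi * k / spec.periodic_beats
        # asymmetric waveform: a generic closed curve, free of the pure
        # sine's reflection symmetry (which would create spurious
        # mirror-phase recurrences in phase space)
        rr = mean_rr + spec.periodic_amp_ms * (
            np.sin(theta) + 0.6 * np.sin(2 * theta + 1.0)
        )
        series = BeatSeries.from_rr(rr)
        truth["period_beats"] = spec.periodic_beats

    else:
        raise ValueError(f"unknown dynamics {spec.dynamics!r}")

    if spec.artifact_rate > 0 or spec.deletion_rate > 0:
        series, cmap = corrupt(series, spec.artifact_rate, spec.deletion_rate,
                               seed=spec.seed + 1)
        truth["corruption"] = cmap
    return series, truth


def corrupt(
    series: BeatSeries,
    artifact_rate: float,
    deletion_rate: float,
    seed: int = 0,
) -> tuple[BeatSeries, dict]:
    """Inject beat-detector errors; return the corrupted series and a map.

    Insertions split a randomly chosen interval at a fraction drawn from
    U(0.2, 0.6) — a noise spike detected mid-interval; deletions merge a
    beat into its successor (a missed detection).  The map records the
    position of every change in the *output* interval indexing, plus
    which output intervals carry corrupted values.
    """
    rng = np.random.default_rng(seed)
    rr = list(series.rr)
    n0 = len(rr)
    if artifact_rate == 0 and deletion_rate == 0:
        return series, {"n_inserted": 0, "n_deleted": 0, "inserted": [],
                        "deleted_at": [], "labels": ["clean"] * n0}
    # per-output-interval provenance: clean | merged | spurious | shortened
    labels = ["clean"] * n0

    n_del = int(round(deletion_rate * n0))
    n_ins = int(round(artifact_rate * n0))

    deleted = []
    for _ in range(n_del):
        if len(rr) < 3:
            break
        k = int(rng.integers(0, len(rr) - 1))
        rr[k] = rr[k] + rr[k + 1]
        del rr[k + 1]
        labels[k] = "merged"
        del labels[k + 1]
        deleted.append(k)

    inserted = []
    for _ in range(n_ins):
        k = int(rng.integers(0, len(rr)))
        f = float(rng.uniform(0.2, 0.6))
        whole = rr[k]
        rr[k] = f * whole
        rr.insert(k + 1, (1.0 - f) * whole)
        prior = labels[k]
        labels[k] = "spurious"
        labels.insert(k + 1, "shortened" if prior == "clean" else prior)
        inserted.append({"index": k, "fraction": f})

    cmap = {
        "n_inserted": len(inserted),
        "n_deleted": len(deleted),
        "inserted": inserted,
        "deleted_at": deleted,
        "labels": labels,
    }
    return BeatSeries.from_rr(np.asarray(rr)), cmap


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative/additive shifts applied to one group's recordings."""

    sd_scale: float = 1.0            # scales gaussian HR fluctuation (SDNN family)
    modulation_scale: float = 1.0    # scales oscillatory amplitudes (LF/HF powers)
    mean_shift_bpm: float = 0.0


def gen_cohort(
    root: str | Path,
    n_per_group: int,
    group_effects: dict[str, GroupEffect],
    seed: int = 0,
    base_spec: SyntheticSpec | None = None,
) -> dict[str, list[Path]]:
    """Write per-group folders of RR-dialect recordings.

    Each group's recordings share the base spec with that group's effect
    applied; per-recording seeds derive deterministically from ``seed``.
    A ground-truth JSON is written next to each folder.
    """
    if len(group_effects) < 2:
        raise ValueError("need at least two groups")
    root = Path(root)
    base = base_spec or SyntheticSpec()
    written: dict[str, list[Path]] = {}
    for g_idx, (group, eff) in enumerate(sorted(group_effects.items())):
        folder = root / group
        folder.mkdir(parents=True, exist_ok=True)
        paths, truths = [], {}
        for r in range(n_per_group):
            spec = replace(
                base,
                sd_hr=base.sd_hr * eff.sd_scale,
                modulation=tuple(
                    (f, a * eff.modulation_scale) for f, a in base.modulation
                ),
                mean_hr=base.mean_hr + eff.mean_shift_bpm,
                seed=(seed * 100003 + g_idx * 1009 + r) % 2**31,
            )
            series, truth = gen_rr(spec)
            path = folder / f"rec{r:03d}.txt"
            write_rr_file(series, path)
            paths.append(path)
            truths[path.name] = truth
        with open(root / f"{group}_truth.json", "w") as fh:
            json.dump(truths, fh, indent=1)
        written[group] = paths
    return written
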