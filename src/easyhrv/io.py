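"""Recording discovery and RR-file parsing.

Two ASCII dialects are supported:

``rr``
    One interbeat interval per line, in seconds (the default).  The first
    value is treated as the interval preceding the first counted beat, so
    interval count equals line count.
``ascii_beats``
    One beat occurrence time per line, in seconds; times are shifted so
    the first beat is at 0.

Other device dialects (WFDB, Polar, Suunto, EDF+, Ambit) are extension
points: register a reader with :func:`register_reader`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .series import BeatSeries

__all__ = [
    "Recording",
    "Cohort",
    "load_rr_file",
    "write_rr_file",
    "discover_cohort",
    "register_reader",
]


@dataclass(frozen=True)
class Recording:
    """One recording: file-derived id, folder-derived group label, beats."""

    id: str
    group: str
    series: BeatSeries

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError("group label must be non-empty")


@dataclass(frozen=True)
class Cohort:
    """All recordings of a study, with the ordered group labels."""

    recordings: tuple[Recording, ...]
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        for rec in self.recordings:
            if rec.group not in self.groups:
                raise ValueError(f"recording {rec.id!r} has unknown group {rec.group!r}")

    def __len__(self) -> int:
        return len(self.recordings)


def _parse_column(path: Path) -> np.ndarray:
    values = []
    with open(path, "r", encoding="ascii", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            try:
                values.append(float(stripped))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {stripped!r} at line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path}: file contains no numeric rows")
    return np.asarray(values, dtype=float)


def load_rr_file(path: str | Path, dialect: str = "rr") -> BeatSeries:
    """Parse a single-column ASCII beat file into a :class:`BeatSeries`.

    Parameters
    ----------
    path : path to an existing, non-empty ASCII file.
    dialect : ``"rr"`` (intervals in seconds) or ``"ascii_beats"``
        (beat times in seconds).  A dialect registered through
        :func:`register_reader` may also be named.
    """
    path = Path(path)
    if dialect in _READERS:
        return _READERS[dialect](path)
    raise ValueError(
        f"unknown dialect {dialect!r}; available: {sorted(_READERS)}"
    )


def _read_rr(path: Path) -> BeatSeries:
    col = _parse_column(path)
    if np.any(col <= 0):
        bad = int(np.argmax(col <= 0))
        raise ValueError(f"{path}: non-positive interval at index {bad}")
    return BeatSeries.from_rr(col * 1000.0)


def _read_ascii_beats(path: Path) -> BeatSeries:
    col = _parse_column(path)
    if col.size < 2:
        raise ValueError(f"{path}: need at least two beat times")
    return BeatSeries(col - col[0])


_READERS: dict[str, Callable[[Path], BeatSeries]] = {
    "rr": _read_rr,
    "ascii_beats": _read_ascii_beats,
}


def register_reader(dialect: str, reader: Callable[[Path], BeatSeries]) -> None:
    """Register a reader for an additional file dialect.

    The reader takes a path and returns a :class:`BeatSeries`; this is the
    extension point for binary/device formats not shipped here.
    """
    _READERS[dialect] = reader


def write_rr_file(series: BeatSeries, path: str | Path) -> None:
    """Write a series in the ``rr`` dialect (one interval in s per line)."""
    path = Path(path)
    with open(path, "w", encoding="ascii") as fh:
        for rr_ms in series.rr:
            fh.write(f"{rr_ms / 1000.0:.9f}\n")


def discover_cohort(
    folders: Sequence[str | Path], dialect: str = "rr"
) -> Cohort:
    """Load every regular file in each folder as one recording.

    The terminal folder name becomes the group label.  Files and groups
    are ordered lexicographically so load order cannot affect downstream
    results.  Only the top level of each folder is read.
    """
    if not folders:
        raise ValueError("need at least one folder")
    paths = [Path(f) for f in folders]
    for p in paths:
        if not p.is_dir():
            raise FileNotFoundError(f"folder not found: {p}")
    labels = [p.resolve().name for p in paths]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(
            f"duplicate terminal folder names give ambiguous group labels: {dupes}"
        )

    order = np.argsort(labels)
    recordings: list[Recording] = []
    groups: list[str] = []
    for k in order:
        folder, label = paths[k], labels[k]
        files = sorted(f for f in folder.iterdir() if f.is_file())
        if not files:
            warnings.warn(f"folder {folder} is empty; group {label!r} dropped")
            continue
        groups.append(label)
        for f in files:
            recordings.append(Recording(id=f.name, group=label, series=load_rr_file(f, dialect)))
    return Cohort(recordings=tuple(recordings), groups=tuple(groups))
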