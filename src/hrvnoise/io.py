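"""Tachogram containers, RR-interval CSV I/O and 5-min segment sampling.

A *tachogram* is the ordered sequence of heart-beat times together with the
derived beat-to-beat (RR) intervals.  Beat times are kept in seconds, RR
intervals in milliseconds throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Tachogram",
    "Segment",
    "read_rr_csv",
    "write_rr_csv",
    "sample_segments",
    "write_results",
    "read_results",
]

_RR_TOL_MS = 1e-9


@dataclass(frozen=True)
class Tachogram:
    """Beat times (s, strictly increasing) and RR intervals (ms).

    ``rr[i]`` is the interval ending at ``beat_times[i + 1]``; the two arrays
    therefore satisfy ``len(rr) == len(beat_times) - 1`` and
    ``rr = diff(beat_times) * 1000``.
    """

    beat_times: np.ndarray
    rr: np.ndarray
    recording_id: str = ""

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        rr = np.asarray(self.rr, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "rr", rr)
        if bt.ndim != 1 or rr.ndim != 1:
            raise ValueError("beat_times and rr must be 1-D arrays")
        if len(rr) != len(bt) - 1:
            raise ValueError(
                f"length mismatch: {len(rr)} intervals for {len(bt)} beats"
            )
        d = np.diff(bt)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0))
            raise ValueError(f"non-monotone beat times at index {i}")
        if np.any(rr <= 0):
            i = int(np.argmax(rr <= 0))
            raise ValueError(f"non-positive interval at index {i}")
        if np.max(np.abs(rr - d * 1000.0)) > _RR_TOL_MS:
            raise ValueError("rr inconsistent with beat-time differences")

    @classmethod
    def from_beat_times(cls, beat_times, recording_id: str = "") -> "Tachogram":
        bt = np.asarray(beat_times, dtype=float)
        return cls(bt, np.diff(bt) * 1000.0, recording_id)

    @classmethod
    def from_rr(cls, rr_ms, t0: float = 0.0, recording_id: str = "") -> "Tachogram":
        """Build from RR intervals alone; beat times by cumulative sum from t0."""
        rr = np.asarray(rr_ms, dtype=float)
        bt = t0 + np.concatenate([[0.0], np.cumsum(rr) / 1000.0])
        return cls(bt, np.diff(bt) * 1000.0, recording_id)

    @property
    def duration(self) -> float:
        """Recording span in seconds (first to last beat)."""
        return float(self.beat_times[-1] - self.beat_times[0])

    def __len__(self) -> int:
        return len(self.beat_times)


@dataclass(frozen=True)
class Segment:
    """One analysis window cut from a recording.

    The window is half-open: beats at ``t_start + window_length`` are
    excluded.
    """

    tachogram: Tachogram
    window_length: float = 300.0
    start_index: int = 0

    def __post_init__(self) -> None:
        if self.tachogram.duration > self.window_length:
            raise ValueError("segment beats span more than the window length")

    @property
    def rr(self) -> np.ndarray:
        return self.tachogram.rr

    @property
    def n_beats(self) -> int:
        return len(self.tachogram)


def read_rr_csv(path) -> Tachogram:
    """Read a tachogram from CSV.

    Two accepted layouts (UTF-8, '.' decimal):

    * columns ``t_sec,rr_ms`` — beat time in seconds and the RR interval (ms)
      ending at that beat; the first row's ``rr_ms`` may be empty,
    * single column ``rr_ms`` — beat times reconstructed by cumulative sum
      starting at 0.

    Malformed rows are rejected with their (1-based data) row number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    rec_id = path.stem
    if "t_sec" in df.columns:
        t = pd.to_numeric(df["t_sec"], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(t))
        if bad.size:
            raise ValueError(f"{path}: unparsable beat time at row {bad[0] + 1}")
        d = np.diff(t)
        if np.any(d <= 0):
            i = int(np.argmax(d <= 0)) + 1
            raise ValueError(f"{path}: non-monotone beat time at row {i + 1}")
        tach = Tachogram.from_beat_times(t, rec_id)
        if "rr_ms" in df.columns:
            rr = pd.to_numeric(df["rr_ms"], errors="coerce").to_numpy()[1:]
            ok = np.isfinite(rr)
            if np.any(rr[ok] <= 0):
                i = int(np.flatnonzero(ok)[np.argmax(rr[ok] <= 0)]) + 2
                raise ValueError(f"{path}: non-positive interval at row {i}")
            if np.any(np.abs(rr[ok] - tach.rr[ok]) > 1e-6):
                i = int(np.flatnonzero(ok & (np.abs(rr - tach.rr) > 1e-6))[0]) + 2
                raise ValueError(
                    f"{path}: rr_ms inconsistent with beat times at row {i}"
                )
        return tach
    if "rr_ms" in df.columns:
        rr = pd.to_numeric(df["rr_ms"], errors="coerce").to_numpy()
        bad = np.flatnonzero(~np.isfinite(rr))
        if bad.size:
            raise ValueError(f"{path}: unparsable interval at row {bad[0] + 1}")
        if np.any(rr <= 0):
            i = int(np.argmax(rr <= 0)) + 1
            raise ValueError(f"{path}: non-positive interval at row {i}")
        return Tachogram.from_rr(rr, recording_id=rec_id)
    raise ValueError(f"{path}: expected columns 't_sec,rr_ms' or 'rr_ms'")


def write_rr_csv(tachogram: Tachogram, path) -> None:
    """Write a tachogram in the two-column ``t_sec,rr_ms`` layout."""
    rr_col = np.concatenate([[np.nan], tachogram.rr])
    pd.DataFrame({"t_sec": tachogram.beat_times, "rr_ms": rr_col}).to_csv(
        path, index=False
    )


def valid_start_indices(tachogram: Tachogram, window: float) -> np.ndarray:
    """Beats with at least ``window`` seconds of recording remaining."""
    remaining = tachogram.beat_times[-1] - tachogram.beat_times
    return np.flatnonzero(remaining >= window)


def extract_segment(
    tachogram: Tachogram, start_index: int, window: float = 300.0
) -> Segment:
    """All beats in the half-open window following the start beat."""
    t0 = tachogram.beat_times[start_index]
    mask = (tachogram.beat_times >= t0) & (tachogram.beat_times < t0 + window)
    sub = Tachogram.from_beat_times(
        tachogram.beat_times[mask], tachogram.recording_id
    )
    return Segment(sub, window_length=window, start_index=int(start_index))


def sample_segments(
    cohort: list[Tachogram],
    n: int,
    window: float = 300.0,
    seed: int | np.random.Generator = 0,
) -> list[Segment]:
    """Draw ``n`` (possibly overlapping) windows from a cohort of recordings.

    Each draw picks a recording uniformly at random (with replacement,
    unweighted by recording length), then a start beat uniformly among beats
    with at least ``window`` seconds of recording remaining, and includes all
    beats in the following half-open window.  Recordings shorter than the
    window are excluded from the draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    eligible = [
        (tach, valid_start_indices(tach, window))
        for tach in cohort
        if valid_start_indices(tach, window).size > 0
    ]
    if not eligible:
        raise ValueError(f"no recording is at least {window} s long")
    segments: list[Segment] = []
    rec_choice = rng.integers(0, len(eligible), size=n)
    for k in rec_choice:
        tach, starts = eligible[k]
        start = int(starts[rng.integers(0, len(starts))])
        segments.append(extract_segment(tach, start, window))
    return segments


def write_results(tables: dict[str, pd.DataFrame], out_dir) -> list[Path]:
    """Write named result tables as tidy CSV files.

    Returns the list of written paths.  Numeric fields survive a
    write-then-read round trip at full precision (shortest-repr floats).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        safe = name.replace("/", "_")
        path = out_dir / f"{safe}.csv"
        table.to_csv(path, index=False)
        written.append(path)
    return written


def read_results(path) -> pd.DataFrame:
    """Paired reader for :func:`write_results` output."""
    return pd.read_csv(path)
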