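"""Data model and I/O for single-cell tracking tables.

A :class:`Track` is one cell's uniformly sampled 2D trajectory (positions in
µm at a fixed frame interval ``dt`` in minutes) together with the identifiers
needed for hierarchical analysis: the cell line it came from, the disease
group of that line, and the substrate condition (ECM protein and coating
concentration) it migrated on.  A :class:`TrackSet` is a cohort of such
tracks plus the expected number of frames per complete track.

The canonical on-disk form is a long CSV, one row per (cell, frame):

    cell_id, line_id, group, substrate, concentration_ugml, frame, x_um, y_um

Coordinates are never smoothed or imputed here: a cell that left the field
of view mid-experiment simply has fewer (or non-contiguous) frames and is
flagged incomplete, to be dropped by :func:`filter_complete` — mirroring the
standard practice of analysing only cells tracked for the full observation
window.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("patient", "control")
SUBSTRATES = ("TCP", "collagenI", "collagenIV", "fibronectin", "laminin",
              "vitronectin")
CONCENTRATIONS = (0.0, 10.0, 50.0, 100.0)

#: canonical CSV column order
TRACK_COLUMNS = ["cell_id", "line_id", "group", "substrate",
                 "concentration_ugml", "frame", "x_um", "y_um"]


class TrackFormatError(ValueError):
    """A tracking table is missing required columns or is not parseable."""


class TrackValidationError(ValueError):
    """Track contents violate the data model (duplicated frames, etc.)."""


@dataclass(frozen=True)
class Track:
    """One cell's 2D trajectory, sampled every ``dt`` minutes.

    Parameters
    ----------
    positions
        ``(n, 2)`` array of (x, y) coordinates in µm, ordered by time.
    frames
        Original integer frame indices; defaults to ``0..n-1``.  A gap in the
        frame indices marks the track incomplete (no interpolation is ever
        applied).
    """

    cell_id: str
    line_id: str
    group: str
    positions: np.ndarray
    dt: float = 30.0
    substrate: str = "TCP"
    concentration: float = 0.0
    frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2:
            raise TrackValidationError(
                f"track {self.cell_id}: positions must be (n, 2), got {pos.shape}")
        if pos.shape[0] < 2:
            raise TrackValidationError(
                f"track {self.cell_id}: need at least 2 positions, got {pos.shape[0]}")
        if not np.all(np.isfinite(pos)):
            raise TrackValidationError(
                f"track {self.cell_id}: non-finite coordinates")
        if not self.dt > 0:
            raise TrackValidationError(f"track {self.cell_id}: dt must be > 0")
        if self.group not in GROUPS:
            raise TrackValidationError(
                f"track {self.cell_id}: unknown group {self.group!r}")
        if self.substrate not in SUBSTRATES:
            raise TrackValidationError(
                f"track {self.cell_id}: unknown substrate {self.substrate!r}")
        object.__setattr__(self, "positions", pos)
        frames = self.frames
        if frames is None:
            frames = np.arange(pos.shape[0])
        else:
            frames = np.asarray(frames, dtype=int)
            if frames.shape[0] != pos.shape[0]:
                raise TrackValidationError(
                    f"track {self.cell_id}: {frames.shape[0]} frame indices "
                    f"for {pos.shape[0]} positions")
            if np.any(np.diff(frames) <= 0):
                raise TrackValidationError(
                    f"track {self.cell_id}: duplicated or non-monotonic frame index")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def condition(self) -> tuple[str, str, float]:
        """(group, substrate, concentration) factor combination."""
        return (self.group, self.substrate, self.concentration)

    def is_complete(self, n_frames_expected: int) -> bool:
        """True if the cell was tracked at every frame 0..n_frames_expected-1."""
        return (self.n_frames == n_frames_expected
                and bool(np.array_equal(
                    self.frames, np.arange(n_frames_expected))))


@dataclass
class TrackSet:
    """A cohort of tracks with a declared frame count for complete tracks."""

    tracks: list[Track]
    dt: float = 30.0
    n_frames_expected: int = 48

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def by_condition(self) -> dict[tuple[str, str, float], list[Track]]:
        out: dict[tuple[str, str, float], list[Track]] = {}
        for t in self.tracks:
            out.setdefault(t.condition, []).append(t)
        return out

    def by_line(self) -> dict[tuple[str, str, str, float], list[Track]]:
        """Group tracks by (group, line, substrate, concentration)."""
        out: dict[tuple[str, str, str, float], list[Track]] = {}
        for t in self.tracks:
            key = (t.group, t.line_id, t.substrate, t.concentration)
            out.setdefault(key, []).append(t)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks:
            rows.append(pd.DataFrame({
                "cell_id": t.cell_id,
                "line_id": t.line_id,
                "group": t.group,
                "substrate": t.substrate,
                "concentration_ugml": t.concentration,
                "frame": t.frames,
                "x_um": t.positions[:, 0],
                "y_um": t.positions[:, 1],
            }))
        if not rows:
            return pd.DataFrame(columns=TRACK_COLUMNS)
        return pd.concat(rows, ignore_index=True)[TRACK_COLUMNS]


def _tracks_from_frame(df: pd.DataFrame, dt: float) -> list[Track]:
    tracks = []
    id_cols = ["cell_id", "line_id", "group", "substrate", "concentration_ugml"]
    for key, sub in df.groupby(id_cols, sort=False):
        cell_id, line_id, group, substrate, conc = key
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy(dtype=int)
        if np.any(np.diff(frames) == 0):
            raise TrackValidationError(
                f"track {cell_id}: duplicated frame index in input table")
        tracks.append(Track(
            cell_id=str(cell_id), line_id=str(line_id), group=str(group),
            substrate=str(substrate), concentration=float(conc),
            positions=sub[["x_um", "y_um"]].to_numpy(dtype=float),
            dt=dt, frames=frames))
    return tracks


def read_tracks(path: str | Path, dt: float | None = None,
                n_frames_expected: int | None = None) -> TrackSet:
    """Read a long-format tracking CSV into a :class:`TrackSet`.

    ``dt`` (minutes) and ``n_frames_expected`` default to values from a JSON
    sidecar ``<path>.meta.json`` written by :func:`write_tracks`, falling back
    to 30 min / 48 frames.  Frames of each cell are sorted by frame index;
    coordinates pass through untouched (µm in, µm out).
    """
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        dt = meta.get("dt", 30.0) if dt is None else dt
        if n_frames_expected is None:
            n_frames_expected = meta.get("n_frames_expected", 48)
    dt = 30.0 if dt is None else float(dt)
    n_frames_expected = 48 if n_frames_expected is None else int(n_frames_expected)

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(
            f"{path}: missing required columns {missing}; found {list(df.columns)}")
    return TrackSet(tracks=_tracks_from_frame(df, dt), dt=dt,
                    n_frames_expected=n_frames_expected)


def write_tracks(ts: TrackSet, path: str | Path) -> Path:
    """Write a :class:`TrackSet` as the canonical CSV plus a metadata sidecar.

    The dialect is exactly what :func:`read_tracks` accepts; float columns use
    shortest round-trip representation so read∘write reproduces coordinates
    bit-identically.  An empty TrackSet yields a header-only file.
    """
    path = Path(path)
    ts.to_frame().to_csv(path, index=False)
    meta = {"dt": ts.dt, "n_frames_expected": ts.n_frames_expected}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))
    return path


def filter_complete(ts: TrackSet) -> TrackSet:
    """Keep only cells tracked at every expected frame.

    This mirrors the completeness rule applied to live-imaging cohorts: cells
    that leave the field of view (or are lost by the tracker) before the end
    of the observation window are removed, never interpolated.  Removal counts
    are logged per (group, substrate, concentration) combination; a condition
    left empty triggers a warning but not a failure.  Idempotent.
    """
    kept, removed = [], Counter()
    conditions = set()
    for t in ts.tracks:
        conditions.add(t.condition)
        if t.is_complete(ts.n_frames_expected):
            kept.append(t)
        else:
            removed[t.condition] += 1
    for cond, n in sorted(removed.items()):
        logger.info("filter_complete: removed %d incomplete track(s) in %s", n, cond)
    kept_conditions = {t.condition for t in kept}
    for cond in sorted(conditions - kept_conditions):
        warnings.warn(f"filter_complete: no complete tracks left in {cond}",
                      stacklevel=2)
    return TrackSet(tracks=kept, dt=ts.dt, n_frames_expected=ts.n_frames_expected)
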