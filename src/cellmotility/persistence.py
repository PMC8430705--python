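"""Directional-persistence metrics for 2D cell trajectories.

Three lag-indexed summary curves are computed per track:

directionality ratio
    net displacement from the origin divided by the accumulated path length
    at each time point; 1 for a perfectly straight path, decaying toward a
    plateau as the cell turns.

mean squared displacement (MSD)
    the overlapping time-averaged MSD,

        MSD(n) = mean over i of |r(i+n) - r(i)|^2 ,

    whose log–log slope α classifies the motion (α = 1 uncorrelated random
    walk, α = 2 ballistic).

velocity autocorrelation (VAC)
    vac(n) = <v_i · v_{i+n}> / <|v_i|^2>, the normalized correlation of step
    velocity vectors; vac(0) = 1 by construction and the decay rate of the
    fitted exponential defines the persistence time.

Curves are aggregated hierarchically — cells averaged within a cell line,
then mean ± SEM across lines — so that the inferential unit downstream is
the line (the individual), not the cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tracks import Track

CURVE_KINDS = ("directionality_ratio", "msd", "vac")


class ZeroMotionError(ValueError):
    """Raised when a metric is undefined because the cell never moved."""


@dataclass
class CurveSeries:
    """A lag-indexed summary curve with per-lag mean and SEM.

    ``sem`` is NaN for single-track curves (no replication to summarize);
    ``n_units`` records how many cells or lines went into the mean.
    """

    kind: str
    lag_minutes: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_units: int = 1

    def __post_init__(self) -> None:
        if self.kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve kind {self.kind!r}")
        self.lag_minutes = np.asarray(self.lag_minutes, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.lag_minutes) == len(self.mean) == len(self.sem)):
            raise ValueError("lag/mean/sem length mismatch")
        if np.any(np.diff(self.lag_minutes) <= 0):
            raise ValueError("lag_minutes must be strictly increasing")
        if self.kind == "directionality_ratio":
            if np.any((self.mean < -1e-12) | (self.mean > 1 + 1e-9)):
                raise ValueError("directionality ratio outside [0, 1]")
        if self.kind == "msd" and np.any(self.mean < -1e-12):
            raise ValueError("MSD must be non-negative")


@dataclass
class AlphaResult:
    """Slope of the log–log MSD curve and the fit that produced it."""

    alpha: float
    intercept: float
    fit_lag_range: tuple[int, int]
    r_squared: float


def step_vectors(t: Track) -> tuple[np.ndarray, np.ndarray]:
    """Frame-to-frame displacement vectors and their lengths, both in µm.

    Returns ``(vectors, lengths)`` with ``vectors[i] = r(i+1) - r(i)``;
    N positions yield N-1 vectors.
    """
    if t.positions.shape[0] < 2:
        raise ValueError(f"track {t.cell_id}: need >= 2 positions for steps")
    vec = np.diff(t.positions, axis=0)
    return vec, np.linalg.norm(vec, axis=1)


def directionality_ratio_curve(t: Track) -> CurveSeries:
    """Directionality ratio at each time point k >= 1 of a single track.

    ratio(k) = |r(k) - r(0)| / sum of step lengths up to k.  The first point
    is always 1 (one step is trivially straight).  A cell that has not moved
    at all up to k has ratio defined as 1: zero deviation from a straight
    path.  Values are clipped to [0, 1] against rounding at the top end.
    """
    _, lengths = step_vectors(t)
    net = np.linalg.norm(t.positions[1:] - t.positions[0], axis=1)
    accum = np.cumsum(lengths)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(accum > 0, net / np.where(accum > 0, accum, 1.0), 1.0)
    ratio = np.clip(ratio, 0.0, 1.0)
    k = np.arange(1, t.positions.shape[0])
    return CurveSeries(kind="directionality_ratio", lag_minutes=k * t.dt,
                       mean=ratio, sem=np.full_like(ratio, np.nan), n_units=1)


def msd_curve(t: Track, max_lag: int | None = None) -> CurveSeries:
    """Overlapping time-averaged MSD of a single track, lags 1..N-1 (frames).

    MSD(n) averages |r(i+n) - r(i)|^2 over every start frame i the track
    allows, so short lags are estimated from many overlapping intervals and
    long lags from few.  Lag 0 (identically zero) is omitted.
    """
    pos = t.positions
    n_pts = pos.shape[0]
    if n_pts < 3:
        raise ValueError(f"track {t.cell_id}: need >= 3 positions for MSD")
    n_max = n_pts - 1 if max_lag is None else min(max_lag, n_pts - 1)
    vals = np.empty(n_max)
    for n in range(1, n_max + 1):
        d = pos[n:] - pos[:-n]
        vals[n - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    lags = np.arange(1, n_max + 1) * t.dt
    return CurveSeries(kind="msd", lag_minutes=lags, mean=vals,
                       sem=np.full_like(vals, np.nan), n_units=1)


def velocity_autocorrelation(t: Track, max_lag: int | None = None) -> CurveSeries:
    """Normalized velocity autocorrelation of a single track, lags 0..M-1.

    vac(n) = mean_i(v_i · v_{i+n}) / mean_i(|v_i|^2) over the M = N-1 step
    velocity vectors; vac(0) = 1 exactly.  Undefined (raises) for a cell
    with zero motion throughout.
    """
    if t.positions.shape[0] < 3:
        raise ValueError(f"track {t.cell_id}: need >= 3 positions for VAC")
    vec, _ = step_vectors(t)  # dt cancels in the normalization
    m = vec.shape[0]
    denom = np.mean(np.einsum("ij,ij->i", vec, vec))
    if denom == 0.0:
        raise ZeroMotionError(
            f"track {t.cell_id}: velocity autocorrelation undefined for a "
            "track with zero motion")
    n_max = m - 1 if max_lag is None else min(max_lag, m - 1)
    vals = np.empty(n_max + 1)
    for n in range(n_max + 1):
        vals[n] = np.mean(np.einsum("ij,ij->i", vec[: m - n], vec[n:])) / denom
    lags = np.arange(n_max + 1) * t.dt
    return CurveSeries(kind="vac", lag_minutes=lags, mean=vals,
                       sem=np.full_like(vals, np.nan), n_units=1)


def default_alpha_lag_range(n_frames: int) -> tuple[int, int]:
    """Default MSD fit window: frame lags 1 .. floor((n_frames - 1) / 2).

    Long-lag MSD points average very few intervals and are dominated by
    noise, so only the first half of the available lags is fitted (for the
    standard 48-frame track: lags 1..23).
    """
    return (1, (n_frames - 1) // 2)


def loglog_alpha(msd: CurveSeries,
                 fit_lag_range: tuple[int, int] | None = None) -> AlphaResult:
    """Least-squares slope of log MSD vs log lag — the anomalous exponent α.

    ``fit_lag_range`` is an inclusive (first, last) pair of *frame* lags
    (the curve's k-th point is frame lag k); defaults to the first half of
    the available lags.  Non-positive MSD values in the window are dropped
    with a warning; fewer than 3 usable points is an error.
    """
    if msd.kind != "msd":
        raise ValueError(f"expected an MSD curve, got kind {msd.kind!r}")
    n_lags = len(msd.mean)
    if fit_lag_range is None:
        fit_lag_range = default_alpha_lag_range(n_lags + 1)
    first, last = fit_lag_range
    if not (1 <= first < last <= n_lags):
        raise ValueError(f"fit_lag_range {fit_lag_range} outside 1..{n_lags}")
    sel = slice(first - 1, last)
    lags, vals = msd.lag_minutes[sel], msd.mean[sel]
    ok = vals > 0
    if not np.all(ok):
        warnings.warn(f"loglog_alpha: dropping {np.sum(~ok)} non-positive "
                      "MSD value(s) from the fit window", stacklevel=2)
        lags, vals = lags[ok], vals[ok]
    if len(vals) < 3:
        raise ValueError("loglog_alpha: fewer than 3 usable lags")
    lx, ly = np.log(lags), np.log(vals)
    slope, intercept = np.polyfit(lx, ly, 1)
    resid = ly - (slope * lx + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
    return AlphaResult(alpha=float(slope), intercept=float(intercept),
                       fit_lag_range=(first, last), r_squared=float(r2))


def aggregate_curves(curves: Sequence[CurveSeries],
                     line_ids: Sequence[str] | None = None,
                     pooled: bool = False) -> CurveSeries:
    """Average per-cell curves into a group curve, mean ± SEM per lag.

    By default averaging is hierarchical: per-lag mean over cells within
    each line (``line_ids`` labels each curve), then mean and SEM across the
    line means, with ``n_units`` = number of lines.  This matches plotting
    conventions where each symbol is an individual, and differs from the
    pooled-cell mean whenever lines contribute unequal cell counts.  Set
    ``pooled=True`` (or leave ``line_ids`` unset) for a flat mean ± SEM over
    cells.
    """
    if not curves:
        raise ValueError("no curves to aggregate")
    kind = curves[0].kind
    lags = curves[0].lag_minutes
    for c in curves[1:]:
        if c.kind != kind:
            raise ValueError("cannot aggregate curves of different kinds")
        if len(c.lag_minutes) != len(lags) or not np.allclose(c.lag_minutes, lags):
            raise ValueError("mismatched lag grids")
    stack = np.vstack([c.mean for c in curves])
    if pooled or line_ids is None:
        units = stack
    else:
        if len(line_ids) != len(curves):
            raise ValueError("line_ids must label every curve")
        order = sorted(set(line_ids))
        idx = {lid: [i for i, l in enumerate(line_ids) if l == lid]
               for lid in order}
        units = np.vstack([stack[idx[lid]].mean(axis=0) for lid in order])
    n = units.shape[0]
    mean = units.mean(axis=0)
    if kind == "directionality_ratio":
        mean = np.clip(mean, 0.0, 1.0)
    sem = (units.std(axis=0, ddof=1) / np.sqrt(n) if n > 1
           else np.full_like(mean, np.nan))
    return CurveSeries(kind=kind, lag_minutes=lags, mean=mean, sem=sem,
                       n_units=n)
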