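"""Active/idle phase segmentation and turn-angle statistics.

Each step of a trajectory is classified against a per-cell speed threshold

    v_thr = (2 - α) · v̄ ,

where v̄ is the cell's mean speed over the whole track and α its log–log
MSD exponent: the closer a cell is to ballistic motion (α → 2) the lower
the bar for being "active".  Steps with instantaneous speed below v_thr
are idling, steps at or above it are active.  Phase durations are reported
both as totals over the track and as mean bout (maximal consecutive run)
durations.  Turn angles — the absolute angle between consecutive step
vectors, in degrees [0, 180] — are attributed to the phase of the step
preceding the junction by default, i.e. the angle "after" an active or
idling step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .persistence import step_vectors
from .tracks import Track

ACTIVE, IDLE = "active", "idle"


@dataclass
class PhaseResult:
    """Per-step active/idle labels and phase-duration accounting (minutes)."""

    v_thr: float
    step_labels: np.ndarray          # str array, one label per step
    dt: float
    active_bouts: list[float] = field(default_factory=list)
    idle_bouts: list[float] = field(default_factory=list)

    @property
    def n_steps(self) -> int:
        return len(self.step_labels)

    @property
    def active_time(self) -> float:
        return float(np.sum(self.step_labels == ACTIVE) * self.dt)

    @property
    def idle_time(self) -> float:
        return float(np.sum(self.step_labels == IDLE) * self.dt)

    @property
    def mean_active_bout(self) -> float:
        return float(np.mean(self.active_bouts)) if self.active_bouts else float("nan")

    @property
    def mean_idle_bout(self) -> float:
        return float(np.mean(self.idle_bouts)) if self.idle_bouts else float("nan")


@dataclass
class TurnAngleResult:
    """Absolute turn angles (degrees in [0, 180]) with per-phase attribution."""

    angles: np.ndarray               # degrees, one per usable junction
    phases: np.ndarray               # phase label per junction
    n_skipped: int                   # junctions dropped for a zero-length step

    @property
    def mean_active_angle(self) -> float:
        a = self.angles[self.phases == ACTIVE]
        return float(a.mean()) if len(a) else float("nan")

    @property
    def mean_idle_angle(self) -> float:
        a = self.angles[self.phases == IDLE]
        return float(a.mean()) if len(a) else float("nan")


def mean_speed(t: Track) -> float:
    """Mean instantaneous speed over the whole trajectory, µm/min."""
    _, lengths = step_vectors(t)
    return float(lengths.mean() / t.dt)


def speed_threshold(alpha: float, v_bar: float) -> float:
    """Active/idle speed threshold v_thr = (2 - α)·v̄ in µm/min.

    For a fully directional cell (α = 2) the threshold is 0: such a cell
    never idles.  α > 2 (possible on noisy fits) would make the threshold
    negative, so it is clamped at 0 with a warning.
    """
    if v_bar < 0:
        raise ValueError("mean speed must be non-negative")
    v_thr = (2.0 - alpha) * v_bar
    if v_thr < 0:
        warnings.warn(f"speed_threshold: alpha = {alpha:.3g} > 2; "
                      "clamping threshold at 0", stacklevel=2)
        v_thr = 0.0
    return v_thr


def _bouts(labels: np.ndarray, which: str, dt: float) -> list[float]:
    out, run = [], 0
    for lab in labels:
        if lab == which:
            run += 1
        elif run:
            out.append(run * dt)
            run = 0
    if run:
        out.append(run * dt)
    return out


def segment_phases(t: Track, v_thr: float) -> PhaseResult:
    """Label every step active (speed >= v_thr) or idle (speed < v_thr).

    Instantaneous speed is step length / dt, so the comparison is
    dimensionally a speed against a speed (equivalently step length against
    v_thr·dt).  Total phase times are label counts × dt; bouts are maximal
    runs of one label.
    """
    if v_thr < 0:
        raise ValueError("v_thr must be non-negative")
    _, lengths = step_vectors(t)
    speeds = lengths / t.dt
    labels = np.where(speeds >= v_thr, ACTIVE, IDLE)
    return PhaseResult(v_thr=float(v_thr), step_labels=labels, dt=t.dt,
                       active_bouts=_bouts(labels, ACTIVE, t.dt),
                       idle_bouts=_bouts(labels, IDLE, t.dt))


def turn_angles(t: Track, p: PhaseResult,
                attribution: str = "preceding") -> TurnAngleResult:
    """Absolute turn angle at every junction between consecutive steps.

    θ is the unsigned angle between step i and step i+1 (degrees, [0, 180]):
    0 is straight continuation, 180 a full reversal.  A junction where
    either step has zero length carries no direction and is skipped (tallied
    in ``n_skipped``).  ``attribution`` decides which step's phase the
    junction inherits: ``"preceding"`` (default — the turn made after that
    phase) or ``"following"``.
    """
    if attribution not in ("preceding", "following"):
        raise ValueError(f"unknown attribution mode {attribution!r}")
    vec, lengths = step_vectors(t)
    if vec.shape[0] < 2:
        raise ValueError(f"track {t.cell_id}: need >= 3 positions for turn angles")
    if len(p.step_labels) != vec.shape[0]:
        raise ValueError("phase labels do not match the track's steps")
    a, b = vec[:-1], vec[1:]
    usable = (lengths[:-1] > 0) & (lengths[1:] > 0)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.einsum("ij,ij->i", a, b)
    theta = np.degrees(np.abs(np.arctan2(cross, dot)))
    phase_idx = np.arange(vec.shape[0] - 1)
    if attribution == "following":
        phase_idx = phase_idx + 1
    phases = p.step_labels[phase_idx]
    return TurnAngleResult(angles=theta[usable], phases=phases[usable],
                           n_skipped=int(np.sum(~usable)))


def analyze_phases(t: Track, alpha: float,
                   attribution: str = "preceding") -> tuple[PhaseResult, TurnAngleResult]:
    """Convenience: threshold from this track's own α and v̄, then segment."""
    v_thr = speed_threshold(alpha, mean_speed(t))
    p = segment_phases(t, v_thr)
    return p, turn_angles(t, p, attribution=attribution)
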