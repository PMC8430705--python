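"""Synthetic persistent-random-walk cohorts with known ground truth.

Tracks are generated from a discrete Ornstein–Uhlenbeck (OU) velocity
process: with frame interval dt and persistence time P,

    v(t + dt) = v(t)·exp(-dt/P) + σ·sqrt(1 - exp(-2·dt/P))·ξ ,

ξ a standard bivariate normal, so the step-velocity autocorrelation is
exactly exp(-n·dt/P) and the fitted persistence time has an analytic
ground truth.  σ is set from the requested mean speed (for a 2D Gaussian
velocity, E|v| = σ·sqrt(π/2)).  Pausing is a two-state Markov chain over
frames — entry probability ``pause_rate``, geometric bouts with mean
``pause_mean_len`` frames — during which the step displacement is scaled
by a near-zero jitter factor.

A cohort spans the full patient/control × substrate × concentration grid
with line-level random effects (each cell line draws its speed once and
keeps it across conditions), and every draw descends deterministically
from a single seed via spawned substreams, so any subset of the cohort is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from scipy.signal import lfilter

from .tracks import CONCENTRATIONS, SUBSTRATES, Track, TrackSet

_SPEED_TO_SIGMA = float(np.sqrt(2.0 / np.pi))  # E|v| = sigma*sqrt(pi/2) in 2D


@dataclass(frozen=True)
class SimParams:
    """Ground-truth parameters for one simulated condition.

    Defaults mirror a high-content live-imaging cohort: 9 cell lines per
    group, ~22 cells per line and condition (≈200 cells per condition per
    group), 48 frames at 30-min intervals (24 h), migration speeds just
    under 1 µm/min with modest between-line variability, and occasional
    pauses of a frame or two.
    """

    n_lines_per_group: int = 9
    n_cells_per_line: int = 22
    n_frames: int = 48
    dt: float = 30.0
    speed_mean: float = 0.8               # µm/min
    speed_sd_between_lines: float = 0.1   # µm/min
    persistence_time: float = 15.0        # minutes
    pause_rate: float = 0.05              # per-frame entry probability
    pause_mean_len: float = 2.0           # frames
    pause_jitter: float = 0.05            # residual motion while paused
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_lines_per_group, self.n_cells_per_line) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_frames < 3:
            raise ValueError("need >= 3 frames")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.persistence_time > 0:
            raise ValueError("persistence_time must be > 0")
        if not 0.0 <= self.pause_rate <= 1.0:
            raise ValueError("pause_rate must be in [0, 1]")
        if self.pause_mean_len < 1.0:
            raise ValueError("pause_mean_len must be >= 1 frame")
        if self.speed_mean < 0 or self.speed_sd_between_lines < 0:
            raise ValueError("speeds must be non-negative")


def _pause_mask(n_steps: int, rate: float, mean_len: float,
                rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov chain over steps: True while paused."""
    mask = np.zeros(n_steps, dtype=bool)
    if rate <= 0.0:
        return mask
    exit_p = 1.0 / mean_len
    u = rng.random(n_steps)
    paused = False
    for i in range(n_steps):
        paused = (u[i] >= exit_p) if paused else (u[i] < rate)
        mask[i] = paused
    return mask


def simulate_track(p: SimParams, rng: np.random.Generator, *,
                   cell_id: str = "c0", line_id: str = "L0",
                   group: str = "control", substrate: str = "TCP",
                   concentration: float = 0.0,
                   return_state: bool = False):
    """Simulate one OU-velocity trajectory of ``p.n_frames`` positions.

    With ``return_state=True`` also returns a dict holding the per-step
    pause mask and pre-pause velocities, for tests that need the injected
    ground truth.
    """
    n_steps = p.n_frames - 1
    sigma = p.speed_mean * _SPEED_TO_SIGMA
    a = float(np.exp(-p.dt / p.persistence_time))
    eps = rng.standard_normal((n_steps, 2))
    v = np.empty((n_steps, 2))
    v[0] = sigma * eps[0]
    if n_steps > 1:
        drive = sigma * np.sqrt(1.0 - a * a) * eps[1:]
        for c in range(2):
            v[1:, c], _ = lfilter([1.0], [1.0, -a], drive[:, c], zi=[a * v[0, c]])
    mask = _pause_mask(n_steps, p.pause_rate, p.pause_mean_len, rng)
    factor = np.where(mask, p.pause_jitter, 1.0)
    steps = v * p.dt * factor[:, None]
    positions = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    track = Track(cell_id=cell_id, line_id=line_id, group=group,
                  substrate=substrate, concentration=concentration,
                  positions=positions, dt=p.dt)
    if return_state:
        return track, {"pause_mask": mask, "velocities": v}
    return track


def simulate_tracks(p: SimParams, n_tracks: int,
                    seed: int | np.random.SeedSequence | None = None,
                    **track_kwargs) -> list[Track]:
    """Simulate ``n_tracks`` i.i.d. tracks, one spawned substream per cell."""
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(p.seed if seed is None else seed))
    tracks = []
    for i, child in enumerate(ss.spawn(n_tracks)):
        kw = dict(track_kwargs)
        kw.setdefault("line_id", "L0")
        kw["cell_id"] = f"{kw['line_id']}_c{i:04d}"
        tracks.append(simulate_track(p, np.random.default_rng(child), **kw))
    return tracks


@dataclass
class CohortSpec:
    """Factor grid plus per-condition parameter overrides for a cohort.

    ``base`` holds one :class:`SimParams` per disease group; ``overrides``
    maps ``(group, substrate, concentration)`` to field updates (e.g. a
    persistence time that rises with ECM concentration for controls only).
    TCP, the uncoated baseline substrate, always carries concentration 0.
    """

    base: dict[str, SimParams]
    substrates: tuple[str, ...] = ("TCP",)
    concentrations: tuple[float, ...] = CONCENTRATIONS
    overrides: dict[tuple[str, str, float], dict] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.base) != {"patient", "control"}:
            raise ValueError("base must define params for 'patient' and 'control'")
        for s in self.substrates:
            if s not in SUBSTRATES:
                raise ValueError(f"unknown substrate {s!r}")

    def conditions(self) -> Iterator[tuple[str, float]]:
        """(substrate, concentration) pairs of the declared grid."""
        for s in self.substrates:
            if s == "TCP":
                yield (s, 0.0)
            else:
                for c in self.concentrations:
                    yield (s, float(c))

    def params_for(self, group: str, substrate: str,
                   concentration: float) -> SimParams:
        p = self.base[group]
        upd = self.overrides.get((group, substrate, float(concentration)))
        return replace(p, **upd) if upd else p

    # -- serialization (YAML/JSON-compatible mapping) -----------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "substrates": list(self.substrates),
            "concentrations": [float(c) for c in self.concentrations],
            "base": {g: asdict(p) for g, p in self.base.items()},
            "overrides": [
                {"group": g, "substrate": s, "concentration": c, "set": dict(u)}
                for (g, s, c), u in self.overrides.items()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        base = {g: SimParams(**p) for g, p in d["base"].items()}
        overrides = {(o["group"], o["substrate"], float(o["concentration"])):
                     dict(o["set"]) for o in d.get("overrides", [])}
        return cls(base=base,
                   substrates=tuple(d.get("substrates", ("TCP",))),
                   concentrations=tuple(d.get("concentrations", CONCENTRATIONS)),
                   overrides=overrides, seed=int(d.get("seed", 0)))

    @classmethod
    def from_file(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_cohort_spec(seed: int = 0, substrates: tuple[str, ...] | None = None,
                        n_lines_per_group: int = 9,
                        n_cells_per_line: int = 22) -> CohortSpec:
    """A cohort mirroring the qualitative disease pattern under study.

    Patient lines are persistently persistent: P = 25 min on every substrate
    and concentration.  Control lines start low (P = 8 min on TCP / at 0
    µg/mL) and gain persistence with ECM concentration (+0.08 min per
    µg/mL), so control persistence rises toward — but stays below — patient
    levels.  Speeds are matched so the contrast is purely in persistence.
    """
    if substrates is None:
        substrates = SUBSTRATES
    base = {
        "patient": SimParams(n_lines_per_group=n_lines_per_group,
                             n_cells_per_line=n_cells_per_line,
                             persistence_time=25.0, seed=seed),
        "control": SimParams(n_lines_per_group=n_lines_per_group,
                             n_cells_per_line=n_cells_per_line,
                             persistence_time=8.0, seed=seed),
    }
    overrides = {}
    for s in substrates:
        if s == "TCP":
            continue
        for c in CONCENTRATIONS:
            overrides[("control", s, float(c))] = {
                "persistence_time": 8.0 + 0.08 * float(c)}
    return CohortSpec(base=base, substrates=tuple(substrates),
                      overrides=overrides, seed=seed)


def simulate_cohort(spec: CohortSpec) -> tuple[TrackSet, pd.DataFrame]:
    """Simulate the full factor grid and return (TrackSet, ground-truth table).

    Each line draws one speed offset from the between-line distribution and
    carries it across every condition (the same biological line is measured
    everywhere).  The ground-truth table records, per line × condition, the
    true persistence time, line speed, and pause parameters.
    """
    root = np.random.SeedSequence(spec.seed)
    n_lines = {g: spec.base[g].n_lines_per_group for g in ("control", "patient")}
    line_seeds = root.spawn(sum(n_lines.values()))
    conditions = list(spec.conditions())

    tracks: list[Track] = []
    truth_rows = []
    i_line = 0
    for group in ("control", "patient"):
        for j in range(n_lines[group]):
            line_id = f"{group[:3]}{j + 1:02d}"
            line_ss = line_seeds[i_line]
            i_line += 1
            # one substream for line-level effects, then one per cell slot
            n_cells = spec.base[group].n_cells_per_line
            children = line_ss.spawn(1 + len(conditions) * n_cells)
            line_rng = np.random.default_rng(children[0])
            speed_offset = (spec.base[group].speed_sd_between_lines
                            * line_rng.standard_normal())
            for ci, (substrate, conc) in enumerate(conditions):
                p = spec.params_for(group, substrate, conc)
                line_speed = max(p.speed_mean + speed_offset, 0.05)
                p_line = replace(p, speed_mean=line_speed)
                truth_rows.append({
                    "group": group, "line_id": line_id, "substrate": substrate,
                    "concentration_ugml": conc,
                    "true_persistence_min": p.persistence_time,
                    "line_speed_um_min": line_speed,
                    "pause_rate": p.pause_rate,
                    "pause_mean_len_frames": p.pause_mean_len,
                })
                for k in range(n_cells):
                    rng = np.random.default_rng(children[1 + ci * n_cells + k])
                    tracks.append(simulate_track(
                        p_line, rng,
                        cell_id=f"{line_id}_{substrate}_{conc:g}_c{k:03d}",
                        line_id=line_id, group=group, substrate=substrate,
                        concentration=conc))
    any_p = spec.base["control"]
    ts = TrackSet(tracks=tracks, dt=any_p.dt, n_frames_expected=any_p.n_frames)
    return ts, pd.DataFrame(truth_rows)
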