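"""End-to-end analysis: tracks → curves → fitted parameters → group stats.

``analyze_trackset`` runs the full per-cell and per-line pipeline:
completeness filtering, directionality-ratio / MSD / VAC curves, one-phase
decay and log–log fits, speed-threshold phase segmentation and turn
angles.  ``compare_metrics`` then applies the inferential layer on the
per-line table: baseline (TCP) patient-vs-control t tests, per-substrate
two-way ANOVAs with Tukey post hocs, and concentration–response slope
comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decay, persistence, phases, stats
from .tracks import TrackSet, filter_complete

logger = logging.getLogger(__name__)

#: per-line parameters carried into the statistical comparisons
LINE_PARAMETERS = [
    "dr_plateau", "dr_half_life_min", "alpha", "persistence_time_min",
    "active_time_min", "idle_time_min", "mean_active_bout_min",
    "mean_idle_bout_min", "active_turn_angle_deg", "idle_turn_angle_deg",
    "mean_speed_um_min",
]


@dataclass
class AnalysisConfig:
    """Tunable choices of the analysis pipeline.

    alpha_fit_range
        inclusive (first, last) frame lags for the log–log MSD fit; None
        means the first half of available lags.
    vthr_mode
        "per_cell": each cell's threshold uses its own α (the formula is
        defined per trajectory); "per_line": all cells of a line share the
        line-level α.
    turn_attribution
        which step's phase a turn-angle junction inherits ("preceding" or
        "following").
    dr_y0_mode
        "free": fit all three decay parameters to DR curves; "fixed": pin
        Y0 at 1 (both DR and VAC start at exactly 1).  VAC fits always pin
        Y0 = 1.
    """

    dt: float = 30.0
    n_frames_expected: int = 48
    alpha_fit_range: tuple[int, int] | None = None
    vthr_mode: str = "per_cell"
    turn_attribution: str = "preceding"
    dr_y0_mode: str = "free"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vthr_mode not in ("per_cell", "per_line"):
            raise ValueError(f"unknown vthr_mode {self.vthr_mode!r}")
        if self.turn_attribution not in ("preceding", "following"):
            raise ValueError(f"unknown turn_attribution {self.turn_attribution!r}")
        if self.dr_y0_mode not in ("free", "fixed"):
            raise ValueError(f"unknown dr_y0_mode {self.dr_y0_mode!r}")
        if self.alpha_fit_range is not None:
            self.alpha_fit_range = tuple(int(v) for v in self.alpha_fit_range)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)


def _curve_rows(curve: persistence.CurveSeries, **labels) -> pd.DataFrame:
    return pd.DataFrame({**labels, "lag_minutes": curve.lag_minutes,
                         "mean": curve.mean, "sem": curve.sem,
                         "n_units": curve.n_units})


def analyze_trackset(ts: TrackSet,
                     config: AnalysisConfig | None = None) -> dict[str, pd.DataFrame]:
    """Run the full persistence/phase pipeline on a cohort.

    Returns a dict of tables:

    ``per_cell``
        one row per complete cell: α, mean speed, v_thr, phase times, bout
        means, turn angles.
    ``per_line``
        one row per line × condition: decay-fit DR plateau/half-life,
        line-level α, persistence time from the line-mean VAC curve, and
        line means of the per-cell phase/turn metrics.
    ``curves``
        long-format line-mean DR/MSD/VAC curves.
    """
    cfg = config or AnalysisConfig()
    complete = filter_complete(ts)
    if len(complete) == 0:
        raise ValueError("no complete tracks to analyze")
    logger.info("analyzing %d complete tracks (%d dropped)",
                len(complete), len(ts) - len(complete))

    cell_rows, curve_frames, line_rows = [], [], []
    n_lags = complete.n_frames_expected
    fit_range = cfg.alpha_fit_range or persistence.default_alpha_lag_range(n_lags)

    for (group, line_id, substrate, conc), tracks in sorted(
            complete.by_line().items()):
        dr_curves, msd_curves, vac_curves = [], [], []
        cell_alphas, cell_metrics = [], []
        for t in tracks:
            msd = persistence.msd_curve(t)
            alpha_res = persistence.loglog_alpha(msd, fit_range)
            dr_curves.append(persistence.directionality_ratio_curve(t))
            msd_curves.append(msd)
            vac_curves.append(persistence.velocity_autocorrelation(t))
            cell_alphas.append(alpha_res.alpha)
            cell_metrics.append((t, alpha_res.alpha))

        line_msd = persistence.aggregate_curves(msd_curves, pooled=True)
        line_alpha = persistence.loglog_alpha(line_msd, fit_range).alpha

        these_rows = []
        for t, cell_alpha in cell_metrics:
            alpha_used = cell_alpha if cfg.vthr_mode == "per_cell" else line_alpha
            v_bar = phases.mean_speed(t)
            v_thr = phases.speed_threshold(alpha_used, v_bar)
            seg = phases.segment_phases(t, v_thr)
            turns = phases.turn_angles(t, seg, attribution=cfg.turn_attribution)
            these_rows.append({
                "cell_id": t.cell_id, "line_id": line_id, "group": group,
                "substrate": substrate, "concentration_ugml": conc,
                "alpha": cell_alpha, "mean_speed_um_min": v_bar,
                "v_thr_um_min": v_thr,
                "active_time_min": seg.active_time,
                "idle_time_min": seg.idle_time,
                "mean_active_bout_min": seg.mean_active_bout,
                "mean_idle_bout_min": seg.mean_idle_bout,
                "active_turn_angle_deg": turns.mean_active_angle,
                "idle_turn_angle_deg": turns.mean_idle_angle,
                "n_junctions": len(turns.angles),
                "n_skipped": turns.n_skipped,
            })
        cell_rows.extend(these_rows)

        line_dr = persistence.aggregate_curves(dr_curves, pooled=True)
        line_vac = persistence.aggregate_curves(vac_curves, pooled=True)
        dr_fit = decay.fit_one_phase_decay(
            line_dr.lag_minutes, line_dr.mean,
            y0_fixed=1.0 if cfg.dr_y0_mode == "fixed" else None)
        vac_fit = decay.fit_one_phase_decay(
            line_vac.lag_minutes, line_vac.mean, y0_fixed=1.0)

        labels = {"group": group, "line_id": line_id, "substrate": substrate,
                  "concentration_ugml": conc}
        sub = pd.DataFrame(these_rows)
        line_rows.append({
            **labels, "n_cells": len(tracks),
            "dr_plateau": dr_fit.plateau,
            "dr_half_life_min": dr_fit.half_life,
            "alpha": line_alpha,
            "alpha_cell_mean": float(np.mean(cell_alphas)),
            "persistence_time_min": vac_fit.persistence_time,
            "mean_speed_um_min": sub["mean_speed_um_min"].mean(),
            "active_time_min": sub["active_time_min"].mean(),
            "idle_time_min": sub["idle_time_min"].mean(),
            "mean_active_bout_min": sub["mean_active_bout_min"].mean(),
            "mean_idle_bout_min": sub["mean_idle_bout_min"].mean(),
            "active_turn_angle_deg": sub["active_turn_angle_deg"].mean(),
            "idle_turn_angle_deg": sub["idle_turn_angle_deg"].mean(),
        })
        for kind, curve in (("directionality_ratio", line_dr),
                            ("msd", line_msd), ("vac", line_vac)):
            curve_frames.append(_curve_rows(curve, kind=kind, **labels))

    return {
        "per_cell": pd.DataFrame(cell_rows),
        "per_line": pd.DataFrame(line_rows),
        "curves": pd.concat(curve_frames, ignore_index=True),
    }


def compare_metrics(per_line: pd.DataFrame,
                    parameters: list[str] | None = None) -> dict:
    """Inferential comparisons on the per-line metric table.

    Returns a JSON-serializable report with, per parameter:

    - ``baseline``: pooled two-sample t test patient vs control on TCP;
    - ``anova``: per non-TCP substrate, a two-way ANOVA (disease ×
      concentration) with Tukey pairwise comparisons;
    - ``slopes``: per substrate, patient and control concentration–response
      slopes and the shared-slope extra-SS F test.
    """
    params = parameters or [p for p in LINE_PARAMETERS if p in per_line.columns]
    missing_groups = {"patient", "control"} - set(per_line["group"].unique())
    if missing_groups:
        raise ValueError(f"missing factor levels: group {sorted(missing_groups)}")
    report: dict = {"baseline_ttests": {}, "anova": {}, "slopes": {}}

    tcp = per_line[per_line["substrate"] == "TCP"]
    for param in params:
        if len(tcp) == 0:
            break
        sub = tcp.dropna(subset=[param])
        v1 = sub.loc[sub["group"] == "patient", param].to_numpy()
        v2 = sub.loc[sub["group"] == "control", param].to_numpy()
        if len(v1) < 2 or len(v2) < 2:
            continue
        r = stats.t_from_line_values(v1, v2)
        report["baseline_ttests"][param] = {
            "patient_mean": float(v1.mean()), "control_mean": float(v2.mean()),
            "t": r.t, "df": r.df, "p": r.p}

    for substrate in sorted(set(per_line["substrate"]) - {"TCP"}):
        sub_all = per_line[per_line["substrate"] == substrate]
        report["anova"][substrate] = {}
        report["slopes"][substrate] = {}
        for param in params:
            sub = sub_all.dropna(subset=[param])
            if sub.empty:
                continue
            try:
                a = stats.two_way_anova(sub[param], sub["group"],
                                        sub["concentration_ugml"])
            except ValueError as exc:
                logger.warning("ANOVA skipped for %s/%s: %s",
                               substrate, param, exc)
                continue
            report["anova"][substrate][param] = {
                "disease": {"F": a.f_disease, "p": a.p_disease},
                "concentration": {"F": a.f_concentration,
                                  "p": a.p_concentration},
                "interaction": {"F": a.f_interaction, "p": a.p_interaction},
                "tukey": a.tukey.to_dict(orient="records"),
            }
            try:
                sc = stats.concentration_slope_compare(
                    sub[param], sub["concentration_ugml"], sub["group"])
            except ValueError as exc:
                logger.warning("slope comparison skipped for %s/%s: %s",
                               substrate, param, exc)
                continue
            report["slopes"][substrate][param] = {
                **{name: {"slope": f.slope, "intercept": f.intercept,
                          "p_slope_vs_zero": f.p_value}
                   for name, f in sc.fits.items()},
                "shared_slope_F": sc.f_shared_slope,
                "shared_slope_p": sc.p_shared_slope,
            }
    return report
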