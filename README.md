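# cellmotility

Quantitative analysis of **directional persistence** in 2D single-cell
migration, built for cohort studies where patient-derived and control cell
lines migrate on different extracellular-matrix (ECM) substrates and the
question is not *how fast* cells move but *how straight*, *how persistent*,
and *how often they pause and turn*.

The package takes uniformly sampled (x, y) tracks (µm, fixed frame interval,
typically 30 min over 24 h) and computes, per cell and per cell line:

- **directionality ratio** — net displacement ÷ accumulated path length at
  every time point, summarized by a one-phase exponential decay
  `Y = (Y0 − Plateau)·e^(−K·X) + Plateau` into a plateau and half-life
  (ln 2 / K);
- **mean squared displacement (MSD)** — the overlapping time-averaged
  `MSD(n) = ⟨|r(i+n) − r(i)|²⟩ᵢ`, with the log–log slope α (α = 1 random,
  α = 2 ballistic);
- **velocity autocorrelation (VAC)** —
  `vac(n) = ⟨vᵢ·vᵢ₊ₙ⟩ / ⟨|vᵢ|²⟩`, fitted by the same one-phase decay; the
  inverse decay rate 1/K is the **persistence time**;
- **active/idle phase segmentation** — each step is classified against the
  per-cell speed threshold `v_thr = (2 − α)·v̄`; total phase times, bout
  durations, and absolute turn angles θ ∈ [0°, 180°] per phase are reported;
- **hierarchical statistics** — cells are averaged within line, and pooled
  two-sample t tests, two-way ANOVA (disease status × ECM concentration)
  with Tukey post hocs, and concentration–response slope comparisons
  (extra sum-of-squares F) run on one value per line.

Because raw tracking data of this kind is rarely deposited, the package
includes a first-class synthetic cohort generator: a discrete
Ornstein–Uhlenbeck velocity process whose step-velocity autocorrelation is
exactly `e^(−n·dt/P)`, so the persistence time P, speed, and pausing
behaviour have known ground truth, with line-level random effects and a
patient/control × substrate × concentration factor grid.

## Worked example

Simulate a small cohort in which patient lines are persistently persistent
(P = 25 min at every concentration) while control lines start at P = 8 min
and gain persistence with ECM concentration, then analyze and compare:

```python
import cellmotility as cm
from cellmotility.simulate import simulate_cohort

spec = cm.default_cohort_spec(seed=7, substrates=("TCP", "fibronectin"),
                              n_lines_per_group=5, n_cells_per_line=10)
tracks, truth = simulate_cohort(spec)          # 500 tracks, 48 frames each
tables = cm.analyze_trackset(tracks)
report = cm.compare_metrics(tables["per_line"])
```

On the uncoated-plastic (TCP) baseline this prints, per line parameter
(patient mean, control mean, pooled t, df, two-tailed p):

```
persistence_time_min: patient 26.305 control 6.787  t=7.62 df=8 p=6.164e-05
alpha:                patient 1.156  control 0.990  t=4.48 df=8 p=0.002044
dr_plateau:           patient 0.232  control 0.193  t=1.91 df=8 p=0.09231
```

The fitted persistence times recover the simulated ground truth (25 vs
8 min), the MSD exponent separates the groups (patient α above 1, control
α at the random-walk value), and on fibronectin the concentration–response
slopes differ (control 0.077 vs patient 0.008 min per µg/mL; shared-slope
F = 7.19, p = 0.011) with a strong disease main effect in the two-way
ANOVA (F = 182.7, p ≈ 9e-15) — the signature of a group that does not
modulate its persistence in response to the ECM.

The same pipeline is scriptable from the shell:

```bash
cellmotility simulate --seed 7 --out runs/sim
cellmotility analyze --tracks runs/sim/tracks.csv --out runs/metrics
cellmotility compare --metrics runs/metrics --out runs/report.json
```

## Layout

- `cellmotility.tracks` — track/cohort data model, CSV I/O, completeness filter
- `cellmotility.persistence` — DR / MSD / VAC curves, α fits, hierarchical averaging
- `cellmotility.decay` — one-phase decay fits, OLS, extra-SS F tests
- `cellmotility.phases` — speed-threshold phase segmentation, turn angles
- `cellmotility.simulate` — OU-velocity cohort generator with ground truth
- `cellmotility.stats` — line-level t tests, two-way ANOVA + Tukey, slope comparisons
- `cellmotility.pipeline` / `cellmotility.cli` — end-to-end orchestration

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
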