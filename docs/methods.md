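# Methods

## The quantities and how they are computed

A track is an ordered sequence of N positions r(0..N−1) in µm at a fixed
frame interval ∆t (minutes); step (velocity) vectors are vᵢ = r(i+1) − r(i),
M = N − 1 of them.  All metrics operate on raw coordinates: no smoothing,
drift correction, or imputation is ever applied, and cells not tracked at
every expected frame are dropped before analysis rather than filled in.

**Directionality ratio.**  At time point k ≥ 1,
DR(k) = |r(k) − r(0)| / Σ_{i<k} |vᵢ| ∈ [0, 1]; DR(1) = 1 by construction.
A cell that has not moved at all up to k is assigned DR = 1 (it has not
deviated from a straight path); this degenerate case matters only for
tracks with an entirely motionless prefix.

**Mean squared displacement.**  The overlapping time-averaged estimator
MSD(n) = (1/(N−n)) Σᵢ |r(i+n) − r(i)|², n = 1..N−1.  Short lags average
many overlapping intervals, long lags few; the log–log slope α is therefore
fitted by ordinary least squares over the first half of the available lags
only (frame lags 1..⌊(N−1)/2⌋, i.e. 1..23 for a 48-frame track) unless the
caller overrides the window.  Non-positive MSD values (stationary tracks)
are dropped from the fit with a warning; fewer than three usable lags is an
error.

**Velocity autocorrelation.**  vac(n) = ⟨vᵢ·vᵢ₊ₙ⟩ᵢ / ⟨|vᵢ|²⟩ᵢ, so vac(0) = 1
exactly and the ∆t in "velocity" cancels; displacement vectors are used
directly.  The normalization is a division by the mean squared step speed —
that is what makes the curve start at 1 and makes an exponential fit of its
decay meaningful.  A track with zero total motion has no defined VAC and
raises an error naming the cell.

**One-phase decay fits.**  Y(X) = (Y0 − Plateau)·e^(−K·X) + Plateau, fitted
by Levenberg–Marquardt least squares (scipy) with the initialization
Y0 ← first value, Plateau ← last value, K ← ln2 / (lag of first midpoint
crossing), which is robust for monotone decays.  Y0 is free by default for
DR fits (three-parameter model) and fixed at 1 for VAC fits, since VAC
starts at exactly 1; DR fits can be switched to the fixed mode.  If the
unconstrained fit returns K ≤ 0, the fit is repeated with K bounded
positive and a warning is issued; an exactly constant series is reported as
degenerate instead of fitted.  Convergence tolerances are 1e-8 (ftol/xtol)
with a 10,000-evaluation cap.  Half-life = ln2/K and persistence time = 1/K
are derived quantities, exact by construction.

**Phase segmentation and turn angles.**  The speed threshold is
v_thr = (2 − α)·v̄ with v̄ the track's mean step speed and α, by default,
that track's own MSD exponent (the formula is defined per trajectory; a
per-line α mode exists).  α > 2 would give a negative threshold and is
clamped to 0 with a warning.  Steps with |vᵢ|/∆t ≥ v_thr are active, below
it idling; the comparison is speed against speed, equivalent to step length
against v_thr·∆t.  Phase durations are reported both as totals (label
counts × ∆t) and as mean bout durations (maximal runs of one label),
because the two summaries answer different questions and published values
of "time in phase" are not always explicit about which is meant.  Turn
angles are θ = |atan2(v_i × v_{i+1}, v_i · v_{i+1})| in degrees; a junction
where either step has zero length carries no direction and is skipped (and
tallied).  Each junction inherits the phase of the *preceding* step by
default — the turn made coming out of that phase — with a "following" mode
available; this attribution is a genuine convention choice, documented
rather than hidden.

**Hierarchical averaging and inference.**  The inferential unit is the cell
line (the individual), never the cell: curves are averaged over cells
within a line, scalar parameters are fitted per line (decay fits on the
line-mean DR and VAC curves; α from the line-mean MSD curve, with the mean
of per-cell α also reported), and per-cell phase/turn metrics are averaged
within line.  t tests use the pooled two-sample statistic with
df = n₁ + n₂ − 2, two-tailed; a summary-statistics form (mean, SEM, n per
group) is provided so published group summaries can be checked without raw
data.  Two-way ANOVA (disease × concentration) is the standard balanced
fixed-effects decomposition via statsmodels, with Tukey HSD over the
disease×concentration cells; unbalanced designs are rejected rather than
silently reweighted.  Concentration–response slopes are compared by the
extra sum-of-squares F test between a shared-slope (separate intercepts)
and a separate-slopes model.

## The synthetic cohort generator

Velocity follows a discrete Ornstein–Uhlenbeck (AR(1)) process: with
a = e^(−∆t/P),

    v(t+∆t) = a·v(t) + σ·√(1−a²)·ξ,   ξ ~ N(0, I₂),

and positions are cumulative sums of v·∆t (velocity held constant within a
frame).  This makes the step-velocity autocorrelation *exactly* e^(−n·∆t/P),
so the persistence time P recovered by the VAC → decay-fit pipeline has an
analytic ground truth — the reason this model was chosen over, say, a
correlated random walk with wrapped-normal turn angles.  σ is set from the
requested mean speed via E|v| = σ√(π/2).  Pausing is a two-state Markov
chain over frames (entry probability `pause_rate`, geometric bouts of mean
`pause_mean_len` frames) that multiplies the step displacement by a
near-zero jitter factor while leaving the velocity memory running.

Defaults mirror a high-content live-imaging cohort: 9 lines per group,
22 cells per line and condition (≈200 cells per condition per group),
48 frames at ∆t = 30 min (24 h), speed 0.8 µm/min with between-line SD
0.1 µm/min, persistence 15 min, pause rate 0.05/frame with 2-frame mean
bouts.  The default two-group cohort encodes the qualitative disease
contrast under study: patient persistence flat at 25 min across substrates
and concentrations, control persistence 8 min at baseline rising by
0.08 min per µg/mL of ECM protein, with matched speeds so the contrast is
purely in persistence.  Seeding is hierarchical (`SeedSequence.spawn`):
one substream per line (line-level speed effect, drawn once and carried
across all conditions, as a real line would be) and one per cell slot, so
any subset of a cohort reproduces bit-identically.

What the generator does *not* emulate: segmentation/tracking noise,
field-of-view exits (tracks are complete by construction; the completeness
filter is exercised with explicitly truncated fixtures), heterogeneity of
persistence within a line, anisotropic or confined motion, and any real
coupling between speed and persistence.  Passing parameter-recovery tests
on this generator therefore demonstrates that the estimator chain is
correct and calibrated for an exponential-VAC walker at the experiment's
sampling — not that real cells follow that model.

## Finite-track behaviour and problem sizes

At the experiment's sampling (∆t = 30 min, 48 frames) the lag-1 VAC of a
weakly persistent cell is tiny (e^(−30/P): 0.0025 at P = 5 min), so
per-line persistence estimates from a handful of cells are noisy and
skewed; the recovery tests quantify the residual bias of the full chain at
P ∈ {5, 10, 25, 50} min using ensembles of 2,000 tracks and require it to
stay within 15%.  Measured this way the bias is a few percent (largest,
≈ +7–10%, at P = 5 where the signal sits in a single lag).  Simulation-
based calibration checks use deliberately scaled cohorts — e.g. 1,000 null
cohorts of 7 lines × 4 cells for the type-I-error check of the line-level
t test, and 9 lines × 12 cells for the end-to-end qualitative contrast —
sizes chosen to keep the whole suite quick to run while leaving the checks
comfortably powered.

## Numerical and design choices

- Frame count defaults to 48 (frames 0..47 over 24 h at 30-min intervals,
  following the convention that frame numbering starts at 0); it is
  configurable wherever it appears.
- DR values are clipped into [0, 1] against floating-point overshoot at the
  straight-line limit; aggregated DR means likewise.
- The α fit window, v_thr α source (per-cell vs per-line), turn-angle
  attribution, and DR Y0 mode are the four analysis options exposed in
  `AnalysisConfig`; every default is stated above and none is data-dependent.
- ANOVA F statistics on an exactly constant response are defined as 0
  (p = 1) rather than NaN, so degenerate fixtures fail loudly downstream
  instead of propagating NaNs.
- The library surface is importable functions plus a thin click CLI
  (`simulate` / `analyze` / `compare`); the CLI adds nothing the functions
  do not expose.

## Known limitations

- Only 2D, uniformly sampled, complete tracks are supported; no drift
  correction or gap handling.
- The decay fitter targets monotone-decay curves; oscillating VAC curves
  (strongly anti-persistent motion) will fit poorly and should be judged by
  their RSS.
- Unbalanced ANOVA designs and mixed-effects models are out of scope; with
  few lines per group the line-level t test is the primary inference.
- Persistence estimates at P ≲ ∆t/4 are at the edge of identifiability at
  30-min sampling; they are reported, but their finite-track bias is the
  dominant error term there.
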