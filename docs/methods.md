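# Methods

This note documents the model implemented in `levotap`, the choices made
where the design was genuinely open, the numerical machinery, what the
synthetic-data generator does and does not emulate, and the known
limitations.  Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Plasma pharmacokinetics

Two compartments with first-order exchange and elimination:

    V1 dc1/dt = -(k21 + ketot) c1 + k12 c2 + i(t)
    V2 dc2/dt =   k21 c1 - k12 c2

- Units: time in minutes, volumes in litres, concentrations in ug/ml
  (numerically identical to mg/L; amounts are converted to mg internally),
  rate constants in L/min.
- The oral dose is modelled as a constant-rate input over an absorption
  window (default 100 mg over 30 min, `InfusionSchedule`), so the
  administered amount is conserved exactly.  When fitting a real or
  synthetic record the window can be set to the time of the observed
  concentration peak.
- The two inter-compartment constants `k12` and `k21` are deliberately
  distinct; forcing symmetry degrades fits of clinical profiles.
- `ketot` lumps direct elimination with transfer into the effect site; the
  plasma equations cannot distinguish the two because the effect site does
  not feed back.
- `V1 = 14 L`, `V2 = 28 L` (0.2 / 0.4 L per kg at a standard 70 kg) are
  fixed, not estimated: with data from a single dose the volumes and rate
  constants are not jointly identifiable.  Every calibrated quantity
  downstream is either independent of the pair or defined relative to
  concentrations simulated with the same pair.
- Estimation: Nelder–Mead on the sum of squared concentration residuals,
  in log-parameter space (positivity for free), from the caller's initial
  guess plus 4 multiplicatively jittered restarts (seeded).  The criterion
  for clinical-shaped profiles has a single practical optimum; the restarts
  make that checkable rather than assumed.  Plain unweighted least squares
  is used; no residual weighting scheme is applied.
- Integration: LSODA with `rtol 1e-8`, `atol 1e-10`, split at the
  absorption-window edges so the solver never steps across the input
  discontinuity.  The test suite checks the solution against the
  matrix-exponential closed form of the linear system to 1e-6.

## Effect site and Hill law

    dc3/dt = (k31/V3) c1 - (ke3/V3) c3,   c3(0) = 0
    c3delay(t) = c3(t - T)
    D = D0 + Dmax c3delay^N / (Dc50^N + c3delay^N)

- Coupling is one-way; plasma kinetics are unaffected by the effect site.
- Only the ratio of `k31/V3` to `ke3/V3` is identifiable: scaling `k31/V3`
  by a factor while scaling `Dc50` by the same factor leaves `D(t)`
  unchanged (verified to 1e-10 in the tests).  `k31/V3` is therefore fixed
  across subjects.  Its default, 0.02 /min, is chosen so that the
  effect-site gain `(k31/V3)/(ke3/V3)` is of order one for clinically
  typical removal rates (0.01–0.035 /min), putting `c3` on the same ug/ml
  scale as plasma — the scale on which half-maximum concentrations of a
  few tenths of a ug/ml are meaningful.
- The delay is implemented as a sample shift with linear interpolation on
  an already-computed signal, not a delay-differential solver; the delay
  is a pure transport lag, so nothing feeds back through it.
- `ke3/V3` carries units of 1/min, consistent with the module's time base.
- The Hill parameters are not estimated automatically.  Clinical tapping
  series carry gross outliers that make unconstrained optimisation
  initial-guess-dependent, so the package provides a deterministic grid
  search (`levotap.gridfit`) with an optional Huber loss and an exported
  loss surface, making near-equivalent parameter combinations visible
  instead of hidden behind a point estimate.

## Basal-ganglia network

Each population is a unit with first-order membrane dynamics and a static
logistic output,

    tau dy/dt = -y + u(t),    z = 1 / (1 + exp(-a (y - u0))),

with `tau = 24 ms`, `a = 4`, `u0 = 1`.  Two segregated action channels
run through: sensory input S and thalamus exciting the cortex (full
`W_CS`, diagonal `W_CT`), cortical lateral inhibition (`l_ij = -1.2`),
cortex and S driving striatal Go (`W_GC`, `W_GS`) and NoGo (`W_NC`,
`W_NS`), NoGo inhibiting GPe (`W_EN`), Go and GPe inhibiting GPi (`W_IG`,
`W_IE`), GPi inhibiting thalamus (`W_TI`), thalamus re-exciting cortex
(`W_TC`) to close the winner-takes-all loop, and an STN unit driven by a
cortical conflict signal (gain `k_E`) that excites both pallidal segments
(`w_ESTN`, `w_ISTN`) and is inhibited by GPe.

Dopamine (`D`) enters three ways:

1. a contrast-enhancing term on Go units,
   `alpha D tanh(1.9 (0.71 C_i + 0.29 G_i - theta_G))` — strongly excited
   channels are potentiated up to `+alpha D`, weakly excited ones
   suppressed down to `-alpha D`, switching around `theta_G = 0.3`;
2. plain inhibition of NoGo (`beta D`, `beta = -1`);
3. inhibition of the cholinergic interneuron (`gamma D`, `gamma = -1`),
   which is tonically active (`I_H = 1.25`) and itself inhibits Go
   (`w_GH = -1`) and excites NoGo (`w_NH = +1`), so falling dopamine
   recruits acetylcholine against movement.  Ablating this unit collapses
   most of the network's dopamine sensitivity (tested): dopamine and
   acetylcholine act in synergy.

Reconstruction choices (where the unit-level contracts left the exact
equations open) and their rationale:

- **Low-pass on the membrane, sigmoid at the output.**  The alternative
  order (sigmoid before the low-pass) has the same fixed points but
  systematically slower switching; the membrane form reproduces the fast
  healthy-state alternation.
- **Bipolar stimulus.**  The cue vector is +1 for the cued channel and -1
  for its rivals: cueing an action actively inhibits the competing
  representation.  With a purely non-negative cue the previous winner's
  thalamo-cortical loop is self-sustaining at high dopamine and alternation
  deadlocks.
- **Smooth contrast switch.**  A hard sign rule keyed on the Go unit's own
  activity is bistable in exactly the wrong way: at low D the Go unit can
  never bootstrap past `theta_G` (movement permanently blocked) and at
  high D the winner never loses its dopamine support (no alternation).
  The implemented switch is a `tanh` (matching the network's sigmoidal
  nonlinearities) of a composite excitation index mixing the cortical
  afferent activity with the Go unit's own activation; the mixing fraction
  (0.71) and slope (1.9) are the reconstruction's two calibration
  constants.
- **Conflict drive to the STN** is the pairwise product of cortical
  activities, which vanishes once a single winner dominates.  A summed
  cortical drive with the printed gains (`k_E = 7`, `w_ISTN = 14`) clamps
  GPi for any active winner and makes selection impossible.
- **Lateral inhibition acts directly** in the cortical input.  A variant
  with the lateral signal low-pass filtered at `tau_L = 120 ms` is
  available (`BgNetwork(filtered_lateral=True)`); the filtered trace of a
  dead winner pins its rival for hundreds of milliseconds, capping
  alternation near 2.3 Hz, so it is not the default.  `tau_L` is carried
  in `BgParams` either way, as are the Hebbian thresholds
  `theta_PRE`/`theta_POST`: no plasticity update runs during a trial.
- **Noise** (`sigma_noise = 0.1`) is available behind a seeded generator
  argument and is off in every calibrated/acceptance path: the model's
  reported operating points are deterministic.

### Calibration

Three constants were fixed once, jointly, against the model's two
published operating points — 2.89 Hz of alternation at D = 0.55 and
1.00 Hz at D = 0.22, both under the *same* action threshold: the action
threshold (0.80), the contrast mix (0.71) and the contrast slope (1.9).
With those frozen values the package computes 2.84 Hz and 0.99 Hz (both
within 0.1 Hz).  No table constant (time constants, gains, weights, tonic
inputs) was altered at any point; the calibration constants are confined
to the protocol threshold and the two constants the reconstruction itself
introduced.

## Tapping protocol

- Action 1 is the tap (finger down, either button), action 2 the
  lift-and-shift; the cue reverses as soon as the cued cortical activity
  crosses the action threshold — the subject re-targets immediately on
  releasing an action.  A 100 ms physiological dead time is inserted once
  after the first selection (movement initiation and detection); because
  the first full cycle is discarded before averaging, steady-state
  frequency does not depend on it.
- Frequency counts tap-down (channel 1) crossings only, matching the
  clinical count of button presses; `frequency_tpm = 60 × frequency_hz`
  by construction.
- Trials run to 8 tap-downs or 15 s of simulated time, whichever comes
  first; a trial with fewer than 3 tap-downs reports frequency 0 (blocked
  movement — a valid outcome at low dopaminergic input, not an error).
  Consecutive steady-state cycles agree to better than 1 % (tested), so
  6 averaged cycles determine the frequency to well inside the reporting
  precision.
- The dopamine-to-frequency curve evaluates each grid point as an
  independent deterministic trial; patient-level simulation interpolates a
  precomputed curve (taps/min, linear, clamped at the grid edges with
  clamping recorded) rather than re-simulating the network at every
  sample time.

## Patient-level simulation and clinical metrics

`simulate_patient` chains dose → plasma → effect site → `D(t)` → tapping
frequency on the clinical sampling grid.  Baseline tapping is the
simulated frequency at `D = D0` (the pre-dose operating point).  Response
metrics follow the clinical convention: latency is the first sample at or
above 1.15 × baseline, the offset the first later sample below it,
duration their difference; a series that returns within the 4 h window is
a wearing-off response (group 2 archetype), one that rises and stays up
is stable (group 1), and a series that never leaves the band cannot be
classified.

## Synthetic-data generator

`levotap.synth` emulates the clinical levodopa test: 100 mg oral dose
after washout, plasma samples at 15-min intervals to 90 min then on the
half hour to 3 h, tapping simultaneously and extended to 4 h.  Ground
truth comes from the published per-patient parameter sets (stable,
wearing-off and borderline archetypes); noise is multiplicative
log-normal on plasma (CV 5 % default, assay-like) and additive Gaussian
on taps/min (SD 5 default, count-jitter-like), both configurable and both
absent from the ground truth attached to each record.  Identical seeds
give identical records.

What the generator does **not** emulate: gross tapping outliers (fatigue,
distraction), inter-patient covariate structure (age, disease duration,
co-therapy), multi-dose regimens, diurnal variation, or assay
non-linearity.  Passing recovery tests on these records therefore shows
the estimation machinery is correct under the stated noise model, not
that it is robust to everything clinical data can do.

## Numerical choices

- Network integration: classical RK4 with `dt = 1 ms`.  The dynamics are
  smooth, so halving the step changes trajectories by ~6e-7 (tolerance
  1e-3); explicit Euler at the same step leaves ~1e-2 discrepancies and
  was rejected.  Threshold crossings are located by linear interpolation
  between steps.
- Kinetic chain: LSODA at `rtol 1e-8` (`1e-7` inside fitting loops, where
  data noise dominates), with the effect-site ODE checked against adaptive
  quadrature of its convolution solution to 1e-4.
- The logistic activation clips its argument at ±500 before
  exponentiation; saturated units are exactly 0 or 1 in floating point.
- Grid-search ties break deterministically on the parameter tuple, so
  rankings are independent of grid ordering.

## Known limitations

- **Narrow dopamine transition.**  With both calibrated operating points
  pinned, the reconstructed network's transition from blocked to
  saturated tapping spans roughly D ∈ [0.21, 0.33] — about half the width
  implied by the published curve.  Consequences, all left as honestly
  failing acceptance tests rather than absorbed by re-tuning: tapping at
  D = 0.20 is fully blocked (0 Hz) instead of ~1 Hz; the frequency at
  D = 0.30 (~2.7 Hz) overshoots the 1–2 Hz parkinsonian band; and the
  curve's very top declines by ~0.07 Hz between D = 0.45 and 0.55 instead
  of being exactly flat.  The root cause is the cholinergic unit's
  operating point: its logistic sits at maximum slope precisely in the
  critical D range, and its contribution to the Go balance (slope ~1 per
  unit D) sharpens the selection bifurcation.  Widening the transition
  would require altering tabulated constants, which this package refuses
  to do.
- **Compressed patient dynamic range.**  Patients whose basal dopaminergic
  effect `D0 ≈ 0.28` sit above the steep knee, where baseline tapping is
  already ~90 % of the saturated rate; a full dose then raises tapping by
  under 15 % and the clinical response criterion never triggers.  Of the
  six published parameter sets, the borderline subject and one
  wearing-off subject reproduce their clinical classification; the others
  read as non-responders.  This is the patient-level face of the narrow
  transition, not an independent defect.
- The effect-site scale convention (`k31/V3 = 0.02 /min`) is a choice, not
  an estimate; only the product structure of the Hill law makes it
  harmless.
- Fixed volumes mean absolute concentrations are only as good as the
  standard-weight assumption; fitted rate constants partially absorb the
  error.
- Two action channels only; the state and weight containers are
  dimensioned generically, but nothing beyond two channels is tested.
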