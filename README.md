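# levotap

A coupled pharmacokinetic–pharmacodynamic–basal-ganglia model of medicated
Parkinson's disease, applied to the alternate finger tapping task.

`levotap` simulates the whole chain from an oral levodopa dose to motor
output: two-compartment plasma kinetics, a brain effect compartment with a
transport delay and a Hill (sigmoid-Emax) concentration–effect law, and a
firing-rate network of the basal ganglia whose winner-takes-all dynamics set
how fast alternate finger taps can be produced.  It is aimed at researchers
in computational neurology and pharmacometrics who want a mechanistic — not
merely curve-fitting — link between plasma levodopa, striatal dopamine
effect, and bradykinesia as measured by the clinical tapping test.

## The model

**Plasma kinetics.** Levodopa enters the central compartment at a constant
rate over an absorption window (mimicking progressive oral assimilation) and
exchanges with a peripheral compartment:

    V1 dc1/dt = -(k21 + ketot) c1 + k12 c2 + i(t)
    V2 dc2/dt =   k21 c1 - k12 c2

`k12`, `k21` and the total body rate constant `ketot` are estimated per
subject by Nelder–Mead least squares on observed plasma concentrations;
`V1`, `V2` are fixed standard-70-kg volumes.

**Effect site.** A one-way effect compartment
`dc3/dt = (k31/V3) c1 − (ke3/V3) c3`, a pure transport delay
`c3delay(t) = c3(t − T)`, and the Hill law

    D = D0 + Dmax · c3delay^N / (Dc50^N + c3delay^N)

map plasma concentration to the dimensionless dopaminergic input `D`
(basal value `D0`, maximum increment `Dmax`, half-maximum concentration
`Dc50`, steepness `N`).

**Basal ganglia.** A firing-rate network with two segregated action
channels — cortex with lateral inhibition, striatal Go/NoGo populations,
GPe, GPi/SNr, STN (hyperdirect conflict brake) and thalamus — where `D`
excites strongly driven Go units and suppresses weak ones, inhibits NoGo,
and inhibits the tonically active cholinergic interneuron that opposes
movement.  The tapping task alternates two actions (tap down / lift and
shift); tapping frequency is the steady-state rate of tap-down threshold
crossings.  At a healthy dopaminergic level (D = 0.55) the model taps at
~2.9 Hz; at a parkinsonian level (D = 0.22) at ~1 Hz; below D ≈ 0.2
movement blocks entirely.

## Worked example

```python
import numpy as np
from levotap import (InfusionSchedule, PkParams, PlasmaPKModel, TimeSeries,
                     simulate_plasma)
from levotap.tapping import run_tapping

for D in (0.55, 0.22):
    r = run_tapping(D)
    print(f"D={D}: {r.frequency_hz:.2f} Hz = {r.frequency_tpm:.0f} taps/min")

sched = InfusionSchedule(dose_ug=100000, duration=30)   # 100 mg over 30 min
times = np.array([15, 30, 45, 60, 75, 90, 120, 150, 180.])
true = PkParams(k12=4.50, k21=3.53, ketot=0.65)
obs, _ = simulate_plasma(true, sched, times)
rng = np.random.default_rng(0)
noisy = TimeSeries(times, obs.values * (1 + 0.02 * rng.standard_normal(9)),
                   "ug/ml")
res = PlasmaPKModel(noisy, sched).fit(PkParams(k12=3., k21=3., ketot=0.4))
print(res.summary())
```

prints

```
D=0.55: 2.84 Hz = 170 taps/min
D=0.22: 0.99 Hz = 59 taps/min
Two-compartment levodopa plasma fit (Nelder-Mead least squares)
----------------------------------------------------------------
  observations            9
  k12   [L/min]               4.6257
  k21   [L/min]               3.6194
  ketot [L/min]               0.6483
  V1, V2 [L] (fixed)      14.0, 28.0
  cost (sum sq. resid)      0.000530
  converged               True (506 iterations, 4 restarts)
```

The tapping lines are the model's two calibrated operating points: fast,
saturated alternation at a healthy dopaminergic input and severe
bradykinesia at a parkinsonian one.  The fit recovers the three free rate
constants of the plasma model from 2 %-noisy observations to within ~3 %.

A command-line interface covers the same pipeline:

```
levotap simulate-pk --params pk.yaml --dose-ug 100000 --duration-min 30 \
        --t-end 240 --out c1.csv
levotap fit-pk --obs obs.csv --init pk.yaml --out fit.json
levotap effect-chain --c1 c1.csv --params effect.yaml --out d.csv
levotap run-tapping --d 0.55 --out tap.json
levotap tapping-curve --d-grid 0.15:0.55:0.01 --out curve.csv
levotap simulate-patient --patient patient.yaml --out patient.csv
levotap synth-patient --archetype wearing-off --seed 1 --out-prefix synth
```

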