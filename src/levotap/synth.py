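"""Synthetic patient generator with the clinical sampling structure.

Emulates the levodopa kinetic-dynamic test: a fasting 100/25 mg
levodopa/benserazide dose after washout, plasma sampling every 15 min for
the first 90 min then every 30 min to 3 h, and simultaneous alternate
finger tapping extended to 4 h.  Ground-truth parameters come from the
published patient archetypes; measurement noise is multiplicative
log-normal on plasma (assay-CV-like) and additive Gaussian on taps/min
(count-jitter-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import EffectParams, InfusionSchedule, PATIENTS, PkParams
from .patient import PatientRecord, simulate_patient
from .timeseries import TimeSeries

__all__ = ["SynthSpec", "make_patient", "PLASMA_SCHEDULE", "TAPPING_SCHEDULE"]

#: plasma sampling grid [min]: every 15 min to 90 min, then on the half hour
#: to 3 h
PLASMA_SCHEDULE = np.array([0, 15, 30, 45, 60, 75, 90, 120, 150, 180], float)
#: tapping performed simultaneously with blood draws, extended to 4 h
TAPPING_SCHEDULE = np.concatenate([PLASMA_SCHEDULE, [210.0, 240.0]])

#: archetype -> parameter pool (printed patients)
_ARCHETYPES = {
    "stable": tuple(p for p in PATIENTS if p.group == 1 and not p.borderline),
    "wearing-off": tuple(p for p in PATIENTS if p.group == 2),
    "borderline": tuple(p for p in PATIENTS if p.borderline),
}


@dataclass(frozen=True)
class SynthSpec:
    """Specification of one synthetic patient draw."""

    archetype: str = "stable"
    noise_plasma_cv: float = 0.05      # multiplicative CV on plasma samples
    noise_tapping_sd: float = 5.0      # additive SD [taps/min]
    seed: int = 0
    dose_ug: float = 100000.0
    absorption_min: float = 30.0
    plasma_times: np.ndarray = field(default_factory=lambda: PLASMA_SCHEDULE)
    tapping_times: np.ndarray = field(default_factory=lambda: TAPPING_SCHEDULE)
    subject: int | None = None         # pin a pool member instead of drawing

    def __post_init__(self) -> None:
        if self.archetype not in _ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}; "
                             f"choose from {sorted(_ARCHETYPES)}")
        if self.noise_plasma_cv < 0 or self.noise_tapping_sd < 0:
            raise ValueError("noise parameters must be >= 0")


def make_patient(spec: SynthSpec, frequency_curve) -> PatientRecord:
    """Draw one synthetic patient record with observed noisy series.

    The ground truth is a seeded draw from the archetype's parameter pool;
    the deterministic chain is simulated on the clinical sampling grids and
    the specified measurement noise added.  The true parameters travel with
    the record (in ``pk`` / ``effect``) so recovery studies can score
    against them.  Identical specs give identical records.
    """
    rng = np.random.default_rng(spec.seed)
    pool = _ARCHETYPES[spec.archetype]
    if spec.subject is None:
        base = pool[int(rng.integers(len(pool)))]
    else:
        matches = [p for p in pool if p.subject == spec.subject]
        if not matches:
            raise ValueError(f"no {spec.archetype} archetype with subject "
                             f"{spec.subject}")
        base = matches[0]

    schedule = InfusionSchedule(dose_ug=spec.dose_ug,
                                duration=spec.absorption_min)
    record = PatientRecord(
        patient_id=f"synth_{spec.archetype}_{spec.seed}",
        group=base.group, schedule=schedule,
        pk=base.pk, effect=base.effect)

    frame = simulate_patient(record, spec.tapping_times, frequency_curve)
    plasma_true = np.interp(spec.plasma_times, frame.time_min, frame.c1)
    taps_true = frame.taps_per_min.to_numpy()

    plasma_obs = plasma_true * np.exp(
        rng.normal(0.0, spec.noise_plasma_cv, plasma_true.shape))
    taps_obs = np.clip(
        taps_true + rng.normal(0.0, spec.noise_tapping_sd, taps_true.shape),
        0.0, None)

    return PatientRecord(
        patient_id=record.patient_id, group=base.group, schedule=schedule,
        pk=base.pk, effect=base.effect,
        observed_plasma=TimeSeries(spec.plasma_times, plasma_obs, "ug/ml",
                                   name="conc_ug_ml"),
        observed_tapping=TimeSeries(spec.tapping_times, taps_obs, "taps/min",
                                    name="taps_per_min"))
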