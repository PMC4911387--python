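"""Per-patient end-to-end simulation and clinical response metrics.

The chain is dose -> plasma (two-compartment) -> effect compartment with
delay -> Hill law -> dopaminergic input D(t) -> tapping frequency, evaluated
at the clinical sampling times over the 4 h test window.  The clinical
read-outs mirror the levodopa kinetic-dynamic test: latency to a >= 15 %
rise of tapping frequency over baseline, duration of the effect (time above
the 15 % band), and the stable / wearing-off classification by whether
tapping returns to the baseline band within the 4 h window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import effect as effect_mod
from . import pk as pk_mod
from .params import EffectParams, InfusionSchedule, PkParams
from .timeseries import TimeSeries

__all__ = ["PatientRecord", "ResponseMetrics", "simulate_patient",
           "response_metrics", "classify_group", "RESPONSE_BAND"]

#: fractional rise over baseline that counts as a clinically significant
#: motor response
RESPONSE_BAND = 0.15


@dataclass(frozen=True)
class PatientRecord:
    """A (possibly synthetic) patient: dosing, model parameters and any
    observed series."""

    patient_id: str
    group: int  # 1 = no motor fluctuations, 2 = motor fluctuations
    schedule: InfusionSchedule
    pk: PkParams
    effect: EffectParams
    observed_plasma: TimeSeries | None = None
    observed_tapping: TimeSeries | None = None

    def __post_init__(self) -> None:
        if self.group not in (1, 2):
            raise ValueError("group must be 1 or 2")


@dataclass(frozen=True)
class ResponseMetrics:
    """Clinical response metrics of a tapping series.

    ``latency`` is the first time tapping rises to >= (1 + band) * baseline;
    ``offset`` the first later time it falls back below that level (NaN if it
    never returns within the window); ``duration = offset - latency``.
    ``responded`` is False when the series never leaves the baseline band.
    """

    baseline: float            # [taps/min]
    latency: float             # [min], NaN when no response
    offset: float              # [min], NaN when no return within window
    duration: float            # [min], NaN when open-ended or no response
    responded: bool
    returned: bool
    classification: str        # "stable" | "wearing-off" | "no-response"


def simulate_patient(record: PatientRecord, sample_times: np.ndarray,
                     frequency_curve, sim_step_min: float = 1.0,
                     ) -> pd.DataFrame:
    """Simulate the full chain for one patient.

    Parameters
    ----------
    record:
        Patient parameters and dosing.
    sample_times:
        Clinical sampling grid [min] for the returned table.
    frequency_curve:
        A callable mapping the dopaminergic input D to tapping frequency
        [taps/min] — typically :class:`levotap.tapping.FrequencyCurve`.
    sim_step_min:
        Internal integration grid spacing for the kinetic chain.

    Returns
    -------
    DataFrame with columns ``time_min``, ``c1``, ``c3delay``, ``D`` and
    ``taps_per_min`` on the requested sampling grid.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    horizon = float(sample_times[-1])
    dense = np.arange(0.0, horizon + sim_step_min / 2, sim_step_min)

    c1, _ = pk_mod.simulate_plasma(record.pk, record.schedule, dense)
    c3 = effect_mod.simulate_effect(c1, record.effect)
    c3d = effect_mod.delay_series(c3, record.effect.T)
    D = effect_mod.hill_effect(c3d.values, record.effect)

    taps = np.asarray([float(frequency_curve(d)) for d in D])
    pick = np.searchsorted(dense, sample_times)
    return pd.DataFrame({
        "time_min": sample_times,
        "c1": c1.values[pick],
        "c3delay": c3d.values[pick],
        "D": D[pick],
        "taps_per_min": taps[pick],
    })


def response_metrics(tapping: TimeSeries, baseline: float,
                     band: float = RESPONSE_BAND) -> ResponseMetrics:
    """Latency, duration and stable / wearing-off classification.

    The series is interpreted at its sample points, the clinical convention:
    latency is the first sample at or above ``(1 + band) * baseline``, the
    offset the first later sample below it.
    """
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    level = (1.0 + band) * baseline
    above = tapping.values >= level
    if not np.any(above):
        return ResponseMetrics(baseline=baseline, latency=np.nan,
                               offset=np.nan, duration=np.nan,
                               responded=False, returned=False,
                               classification="no-response")
    i_on = int(np.argmax(above))
    latency = float(tapping.times[i_on])
    below_after = ~above[i_on:]
    if np.any(below_after):
        i_off = i_on + int(np.argmax(below_after))
        offset = float(tapping.times[i_off])
        return ResponseMetrics(baseline=baseline, latency=latency,
                               offset=offset, duration=offset - latency,
                               responded=True, returned=True,
                               classification="wearing-off")
    return ResponseMetrics(baseline=baseline, latency=latency,
                           offset=np.nan, duration=np.nan,
                           responded=True, returned=False,
                           classification="stable")


def classify_group(metrics: ResponseMetrics) -> int | None:
    """Map response metrics to the clinical group archetype.

    Wearing-off responders (return to the baseline band within the window)
    map to group 2, stable responders to group 1; a series that never
    responded cannot be classified.
    """
    if not metrics.responded:
        return None
    return 2 if metrics.returned else 1
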