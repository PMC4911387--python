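"""Patient-level simulation and clinical response metrics."""

import numpy as np
import pytest

from levotap.params import EffectParams, InfusionSchedule, PATIENTS
from levotap.patient import PatientRecord, classify_group, response_metrics, \
    simulate_patient
from levotap.timeseries import TimeSeries

SAMPLE_TIMES = np.arange(0.0, 241.0, 5.0)


def record_for(pt, schedule, effect=None):
    return PatientRecord(patient_id=pt.label, group=pt.group,
                         schedule=schedule, pk=pt.pk,
                         effect=effect if effect is not None else pt.effect)


class TestResponseMetrics:
    def test_constant_series_is_no_response(self):
        ts = TimeSeries(np.arange(0, 241, 15.0), np.full(17, 100.0),
                        "taps/min")
        m = response_metrics(ts, baseline=100.0)
        assert not m.responded and m.classification == "no-response"
        assert np.isnan(m.latency)

    def test_rise_and_return_hand_traced(self):
        """Five-point toy series: crosses the 15 % band at 30 min, returns
        below it at 120 min, so latency 30, duration 90, wearing-off."""
        base = 100.0
        ts = TimeSeries([0.0, 30.0, 60.0, 90.0, 120.0],
                        base * np.array([1.0, 1.2, 1.3, 1.2, 1.1]),
                        "taps/min")
        m = response_metrics(ts, baseline=base)
        assert m.latency == 30.0
        assert m.offset == 120.0
        assert m.duration == 90.0
        assert m.classification == "wearing-off"

    def test_sustained_rise_is_stable_with_open_duration(self):
        ts = TimeSeries(np.arange(0, 241, 30.0),
                        np.array([100, 110, 150, 150, 150, 150, 150, 150,
                                  150.0]), "taps/min")
        m = response_metrics(ts, baseline=100.0)
        assert m.classification == "stable"
        assert m.latency == 60.0
        assert np.isnan(m.duration)

    def test_invalid_baseline(self):
        ts = TimeSeries([0.0, 60.0], [100.0, 120.0], "taps/min")
        with pytest.raises(ValueError):
            response_metrics(ts, baseline=0.0)


class TestClassifyGroup:
    def test_mapping(self):
        ts = TimeSeries([0.0, 30.0, 60.0, 90.0, 120.0],
                        100 * np.array([1.0, 1.2, 1.3, 1.2, 1.1]), "taps/min")
        wearing = response_metrics(ts, 100.0)
        assert classify_group(wearing) == 2
        flat = response_metrics(
            TimeSeries([0.0, 120.0, 240.0], [100.0, 101.0, 100.0],
                       "taps/min"), 100.0)
        assert classify_group(flat) is None


class TestSimulatePatient:
    def test_negligible_drug_effect_keeps_baseline(self, frequency_curve,
                                                   standard_dose):
        pt = PATIENTS[3]
        effect = pt.effect.replace(Dmax=1e-9, D0=0.27)
        frame = simulate_patient(record_for(pt, standard_dose, effect),
                                 SAMPLE_TIMES, frequency_curve)
        base = frequency_curve(0.27)
        np.testing.assert_allclose(frame.taps_per_min, base, atol=1e-3)

    def test_outputs_cover_requested_grid(self, frequency_curve,
                                          standard_dose):
        frame = simulate_patient(record_for(PATIENTS[0], standard_dose),
                                 SAMPLE_TIMES, frequency_curve)
        np.testing.assert_array_equal(frame.time_min, SAMPLE_TIMES)
        assert set(frame.columns) == {"time_min", "c1", "c3delay", "D",
                                      "taps_per_min"}
        assert frame.D.iloc[0] == pytest.approx(PATIENTS[0].effect.D0)

    def test_wearing_off_patient_returns_to_baseline(self, frequency_curve,
                                                     standard_dose):
        """Group-2 subject 1 (fast effect-site clearance, steep Hill law):
        tapping rises then falls back into the baseline band within 4 h."""
        pt = PATIENTS[3]
        frame = simulate_patient(record_for(pt, standard_dose), SAMPLE_TIMES,
                                 frequency_curve)
        m = response_metrics(
            TimeSeries(frame.time_min.to_numpy(),
                       frame.taps_per_min.to_numpy(), "taps/min"),
            baseline=float(frequency_curve(pt.effect.D0)))
        assert m.classification == "wearing-off"
        assert classify_group(m) == 2

    def test_borderline_patient_classifies_stable(self, frequency_curve,
                                                  standard_dose):
        """Group-1 subject 3 rises strongly from its low basal level and
        has not returned to the band by 240 min."""
        pt = PATIENTS[2]
        frame = simulate_patient(record_for(pt, standard_dose), SAMPLE_TIMES,
                                 frequency_curve)
        m = response_metrics(
            TimeSeries(frame.time_min.to_numpy(),
                       frame.taps_per_min.to_numpy(), "taps/min"),
            baseline=float(frequency_curve(pt.effect.D0)))
        assert m.classification == "stable"

    @staticmethod
    def _duration(effect, frequency_curve, standard_dose):
        """Response duration, right-censored at the 4 h window end when the
        tapping has not yet returned to the baseline band."""
        pt = PATIENTS[3]
        frame = simulate_patient(record_for(pt, standard_dose, effect),
                                 SAMPLE_TIMES, frequency_curve)
        m = response_metrics(
            TimeSeries(frame.time_min.to_numpy(),
                       frame.taps_per_min.to_numpy(), "taps/min"),
            baseline=float(frequency_curve(effect.D0)))
        assert m.responded
        return m.duration if m.returned else SAMPLE_TIMES[-1] - m.latency

    def test_duration_shrinks_with_hill_coefficient(self, frequency_curve,
                                                    standard_dose):
        base = EffectParams(ke3_over_V3=0.05, T=15, D0=0.24, Dmax=0.304,
                            Dc50=0.13, N=2)
        durations = [self._duration(base.replace(N=n), frequency_curve,
                                    standard_dose) for n in (2, 5, 8)]
        assert durations[0] >= durations[1] >= durations[2]
        assert durations[0] > durations[2]

    def test_duration_shrinks_with_effect_clearance(self, frequency_curve,
                                                    standard_dose):
        base = EffectParams(ke3_over_V3=0.03, T=15, D0=0.24, Dmax=0.304,
                            Dc50=0.13, N=7)
        durations = [self._duration(base.replace(ke3_over_V3=k),
                                    frequency_curve, standard_dose)
                     for k in (0.03, 0.04, 0.05)]
        assert durations[0] >= durations[1] >= durations[2]
        assert durations[0] > durations[2]
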