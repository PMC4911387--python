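import numpy as np
import pytest

from levotap.params import InfusionSchedule, PATIENTS
from levotap.tapping import d_to_frequency_curve, run_tapping


@pytest.fixture(scope="session")
def tapping_anchor_055():
    """Tapping trial at the healthy dopaminergic level."""
    return run_tapping(0.55)


@pytest.fixture(scope="session")
def tapping_anchor_022():
    """Tapping trial at the parkinsonian dopaminergic level."""
    return run_tapping(0.22)


@pytest.fixture(scope="session")
def frequency_curve():
    """Coarse D -> frequency curve covering the patient D range."""
    grid = np.array([0.10, 0.15, 0.20, 0.22, 0.25, 0.275, 0.30, 0.35,
                     0.40, 0.45, 0.50, 0.55, 0.60, 0.70, 0.80])
    return d_to_frequency_curve(grid)


@pytest.fixture(scope="session")
def standard_dose():
    """The clinical 100 mg oral dose over a 30 min absorption window."""
    return InfusionSchedule(dose_ug=100000.0, duration=30.0)


@pytest.fixture(params=[p.label for p in PATIENTS])
def patient(request):
    return next(p for p in PATIENTS if p.label == request.param)
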