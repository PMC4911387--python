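"""Parameter sets for the three sub-models and the published patient values.

Units follow one convention throughout the package: time in minutes for the
kinetic chain (milliseconds inside the neural network), volumes in litres,
amounts in micrograms, concentrations in ug/ml, rate constants in L/min as
they are reported for the plasma model and in 1/min for the effect site.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PkParams", "InfusionSchedule", "EffectParams", "BgParams",
    "SynapticWeights", "PatientParams", "PATIENTS",
    "STANDARD_V1", "STANDARD_V2", "DEFAULT_K31_OVER_V3",
]

# Central / peripheral distribution volumes for a standard 70 kg adult
# (roughly 0.2 and 0.4 L/kg, the scale reported for levodopa two-compartment
# fits).  Every calibrated quantity downstream of the plasma model is either
# independent of these or expressed relative to concentrations simulated with
# the same pair, so only the pair's consistency matters, not its exact value.
STANDARD_V1 = 14.0  # [L]
STANDARD_V2 = 28.0  # [L]

# Transfer rate into the effect compartment over its volume, fixed across
# subjects.  Only the ratio of k31/V3 to ke3/V3 is identifiable (a joint
# rescaling of k31/V3 and Dc50 leaves the dopaminergic input unchanged), so
# the package pins it at a value that puts effect-site concentrations on the
# same ug/ml scale as plasma for typical removal rates (ke3/V3 ~ 0.01-0.035
# 1/min), which is the scale on which the published Dc50 values live.
DEFAULT_K31_OVER_V3 = 0.02  # [1/min]


def _require_positive(obj, *names: str) -> None:
    for name in names:
        if not getattr(obj, name) > 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, "
                             f"got {getattr(obj, name)!r}")


@dataclass(frozen=True)
class PkParams:
    """Two-compartment plasma kinetics of levodopa.

    ``k12``/``k21`` are the inter-compartment transfer constants (the two
    directions are deliberately allowed to differ), ``ketot`` the total body
    elimination constant (the sum of direct elimination and transfer into the
    effect site, which is all that the plasma equations can see), ``V1``/``V2``
    the central and peripheral volumes.
    """

    k12: float
    k21: float
    ketot: float
    V1: float = STANDARD_V1
    V2: float = STANDARD_V2

    def __post_init__(self) -> None:
        _require_positive(self, "k12", "k21", "ketot", "V1", "V2")

    def replace(self, **kw) -> "PkParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class InfusionSchedule:
    """Constant-rate absorption window standing in for oral dosing.

    The whole dose enters the central compartment at rate ``dose_ug/duration``
    during ``[t_start, t_start + duration)``, mimicking progressive gastric
    assimilation of an oral tablet.
    """

    dose_ug: float
    duration: float  # [min]
    t_start: float = 0.0  # [min]

    def __post_init__(self) -> None:
        _require_positive(self, "dose_ug", "duration")
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration

    @property
    def rate_ug_min(self) -> float:
        return self.dose_ug / self.duration


@dataclass(frozen=True)
class EffectParams:
    """Effect-compartment kinetics, transport delay and Hill concentration-
    effect law mapping delayed effect-site levodopa to the dopaminergic
    input D of the basal-ganglia network.

    D0 is the basal (pre-dose, endogenous) dopaminergic effect, Dmax the
    maximum levodopa-induced increment, Dc50 the effect-site concentration at
    half-maximum, N the Hill coefficient controlling the steepness of the
    concentration-effect curve.
    """

    ke3_over_V3: float          # [1/min] removal from the effect site
    T: float                    # [min]   pure transport delay
    D0: float                   # [-]
    Dmax: float                 # [-]
    Dc50: float                 # [ug/ml]
    N: float                    # [-] Hill coefficient
    k31_over_V3: float = DEFAULT_K31_OVER_V3  # [1/min], fixed across subjects

    def __post_init__(self) -> None:
        _require_positive(self, "ke3_over_V3", "Dmax", "Dc50", "k31_over_V3")
        if self.N < 1:
            raise ValueError("Hill coefficient N must be >= 1")
        if self.T < 0:
            raise ValueError("delay T must be >= 0")
        if not 0 < self.D0 < self.D0 + self.Dmax <= 1:
            raise ValueError("need 0 < D0 < D0 + Dmax <= 1 "
                             "(D is a normalized modulatory input)")

    def replace(self, **kw) -> "EffectParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class BgParams:
    """Constants of the firing-rate basal-ganglia network.

    ``theta_PRE``/``theta_POST`` belong to the Hebbian plasticity rule of the
    underlying network; they are carried for completeness but no plasticity
    update runs during a tapping trial.
    """

    tau: float = 24.0       # [ms] neuron membrane time constant
    tau_L: float = 120.0    # [ms] cortical lateral-inhibition time constant
    a: float = 4.0          # sigmoid slope
    u0: float = 1.0         # sigmoid central point
    theta_G: float = 0.3    # Go contrast-enhancement threshold
    I_E: float = 1.0        # tonic input, GPe
    I_I: float = 3.0        # tonic input, GPi
    I_H: float = 1.25       # tonic input, cholinergic interneuron
    alpha: float = 1.0      # dopamine gain on Go (contrast-enhancing)
    beta: float = -1.0      # dopamine gain on NoGo (inhibitory)
    gamma: float = -1.0     # dopamine gain on cholinergic interneuron
    sigma_noise: float = 0.1  # noise amplitude (only used when enabled)
    theta_PRE: float = 0.5
    theta_POST: float = 0.5

    def __post_init__(self) -> None:
        _require_positive(self, "tau", "tau_L", "a")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0 (dopamine excites active Go)")
        if self.beta >= 0 or self.gamma >= 0:
            raise ValueError("beta and gamma must be < 0 (dopamine inhibits "
                             "NoGo and the cholinergic interneuron)")

    def replace(self, **kw) -> "BgParams":
        return replace(self, **kw)


def _diag(value: float, n: int) -> np.ndarray:
    return np.eye(n) * value


@dataclass(frozen=True)
class SynapticWeights:
    """Connection strengths of the network, dimensioned for ``n_channels``
    segregated action channels (2 for the alternate tapping task)."""

    n_channels: int = 2
    L: np.ndarray = None          # cortex lateral inhibition (extradiagonal)
    W_CS: np.ndarray = None       # cortex <- sensory
    W_CT: np.ndarray = None       # cortex <- thalamus
    W_GC: np.ndarray = None       # Go <- cortex
    W_GS: np.ndarray = None       # Go <- sensory
    W_NC: np.ndarray = None       # NoGo <- cortex
    W_NS: np.ndarray = None       # NoGo <- sensory
    W_EN: np.ndarray = None       # GPe <- NoGo
    W_IE: np.ndarray = None       # GPi <- GPe
    W_IG: np.ndarray = None       # GPi <- Go
    W_TC: np.ndarray = None       # thalamus <- cortex
    W_TI: np.ndarray = None       # thalamus <- GPi
    w_ESTN: float = 1.0           # GPe <- STN
    w_ISTN: float = 14.0          # GPi <- STN
    k_E: float = 7.0              # STN <- cortex (hyperdirect conflict gain)
    W_STNE: np.ndarray = None     # STN <- GPe (row vector)
    w_GH: float = -1.0            # Go <- cholinergic interneuron
    w_NH: float = 1.0             # NoGo <- cholinergic interneuron

    def __post_init__(self) -> None:
        n = self.n_channels
        if n < 2:
            raise ValueError("need at least 2 action channels")
        defaults = {
            "L": np.full((n, n), -1.2) * (1 - np.eye(n)),
            "W_CS": np.full((n, n), 0.2) + _diag(1.1 - 0.2, n),
            "W_CT": _diag(4.0, n),
            "W_GC": _diag(0.48, n),
            "W_GS": _diag(0.9, n),
            "W_NC": _diag(1.08, n),
            "W_NS": _diag(0.1, n),
            "W_EN": _diag(-2.2, n),
            "W_IE": _diag(-3.0, n),
            "W_IG": _diag(-12.0, n),
            "W_TC": _diag(3.0, n),
            "W_TI": _diag(-3.0, n),
            "W_STNE": np.full(n, -1.0),
        }
        for name, default in defaults.items():
            value = getattr(self, name)
            arr = default if value is None else np.asarray(value, dtype=float)
            object.__setattr__(self, name, arr)
        self._validate_signs()

    def _validate_signs(self) -> None:
        inhibitory = ("L", "W_EN", "W_IE", "W_IG", "W_TI", "W_STNE")
        excitatory = ("W_CS", "W_CT", "W_GC", "W_GS", "W_NC", "W_NS", "W_TC")
        for name in inhibitory:
            if np.any(getattr(self, name) > 0):
                raise ValueError(f"{name} must be non-positive (inhibitory)")
        for name in excitatory:
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be non-negative (excitatory)")
        if self.w_GH > 0:
            raise ValueError("w_GH must be <= 0 (cholinergic inhibition of Go)")
        if self.w_NH < 0 or self.w_ESTN < 0 or self.w_ISTN < 0 or self.k_E < 0:
            raise ValueError("w_NH, w_ESTN, w_ISTN and k_E must be >= 0")


@dataclass(frozen=True)
class PatientParams:
    """One published patient: plasma-kinetic and effect parameters plus the
    clinical group (1 = no motor fluctuations, 2 = motor fluctuations)."""

    group: int
    subject: int
    pk: PkParams
    effect: EffectParams
    borderline: bool = False

    @property
    def label(self) -> str:
        return f"group{self.group}_subject{self.subject}"


def _patient(group, subject, k21, k12, ketot, ke3, T, D0, Dmax, Dc50, N,
             borderline=False) -> PatientParams:
    return PatientParams(
        group=group, subject=subject,
        pk=PkParams(k12=k12, k21=k21, ketot=ketot),
        effect=EffectParams(ke3_over_V3=ke3, T=T, D0=D0, Dmax=Dmax,
                            Dc50=Dc50, N=N),
        borderline=borderline,
    )


#: The six published patients: three "stable" responders (group 1) and three
#: "wearing-off" responders (group 2).  Group 1 subject 3 sits between the
#: two archetypes (high Dc50 and removal rate despite the low Hill slope).
PATIENTS: tuple[PatientParams, ...] = (
    _patient(1, 1, k21=9.11, k12=10.0, ketot=0.80,
             ke3=0.010, T=15, D0=0.29, Dmax=0.50, Dc50=0.25, N=2),
    _patient(1, 2, k21=8.70, k12=7.40, ketot=1.16,
             ke3=0.020, T=0, D0=0.28, Dmax=0.317, Dc50=0.03, N=2),
    _patient(1, 3, k21=1.07, k12=1.75, ketot=0.45,
             ke3=0.025, T=0, D0=0.22, Dmax=0.305, Dc50=0.12, N=2,
             borderline=True),
    _patient(2, 1, k21=3.53, k12=4.50, ketot=0.65,
             ke3=0.030, T=15, D0=0.27, Dmax=0.304, Dc50=0.13, N=7),
    _patient(2, 2, k21=1.26, k12=1.77, ketot=0.58,
             ke3=0.020, T=15, D0=0.279, Dmax=0.31, Dc50=0.38, N=8),
    _patient(2, 3, k21=1.12, k12=1.57, ketot=0.43,
             ke3=0.035, T=0, D0=0.275, Dmax=0.333, Dc50=0.20, N=8),
)
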