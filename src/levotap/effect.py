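"""Effect compartment, transport delay and Hill concentration-effect law.

Plasma levodopa enters a hypothetical brain effect compartment with one-way
coupling (nothing flows back to plasma):

    dc3/dt = (k31/V3) c1(t) - (ke3/V3) c3,     c3(0) = 0

so that c3 is a first-order low-pass of c1 with gain (k31/V3)/(ke3/V3) and is
proportional to c1 in steady state.  A pure transport delay T then shifts c3,
and the delayed concentration drives the dimensionless dopaminergic input

    D = D0 + Dmax * c3d**N / (Dc50**N + c3d**N),

the quantity handed to the basal-ganglia network.  Because only the ratio of
the two effect-site rates is identifiable, rescaling k31/V3 by a factor while
rescaling Dc50 by the same factor leaves D(t) unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .params import EffectParams
from .timeseries import TimeSeries

__all__ = ["simulate_effect", "delay_series", "hill_effect", "effect_chain"]


def simulate_effect(c1: TimeSeries, params: EffectParams,
                    rtol: float = 1e-8, atol: float = 1e-12) -> TimeSeries:
    """Integrate the effect-compartment ODE on the grid of ``c1``.

    The plasma trace is interpolated linearly between its samples, so ``c1``
    should be sampled densely relative to 1/(ke3/V3).
    """
    if c1.unit != "ug/ml":
        raise ValueError(f"expected plasma series in ug/ml, got {c1.unit!r}")
    k31, ke3 = params.k31_over_V3, params.ke3_over_V3
    times, values = c1.times, c1.values

    def rhs(t, y):
        return k31 * np.interp(t, times, values) - ke3 * y[0]

    sol = solve_ivp(rhs, (times[0], times[-1]), [0.0], method="LSODA",
                    t_eval=times, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"effect ODE integration failed: {sol.message}")
    return TimeSeries(times, np.clip(sol.y[0], 0.0, None), "ug/ml", name="c3")


def delay_series(c3: TimeSeries, T: float) -> TimeSeries:
    """Pure transport delay: value at t equals ``c3`` at t - T.

    Before the signal history begins (t < times[0] + T) the output is the
    initial drug-free value, zero for an effect-site trace.
    """
    if T < 0:
        raise ValueError("delay T must be >= 0")
    shifted = np.interp(c3.times - T, c3.times, c3.values,
                        left=c3.values[0] if len(c3) else 0.0)
    return TimeSeries(c3.times, shifted, c3.unit, name="c3delay")


def hill_effect(c3delay, params: EffectParams):
    """Hill law mapping delayed effect-site concentration to the input D.

    Monotone increasing from D0 at zero concentration towards the asymptote
    D0 + Dmax, passing through D0 + Dmax/2 at Dc50 with local slope
    N * Dmax / (4 * Dc50).
    """
    c = np.asarray(c3delay, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    cn = c ** params.N
    D = params.D0 + params.Dmax * cn / (params.Dc50 ** params.N + cn)
    return float(D) if D.ndim == 0 else D


def effect_chain(c1: TimeSeries, params: EffectParams) -> TimeSeries:
    """Plasma to dopaminergic input: effect compartment, delay, Hill law."""
    c3 = simulate_effect(c1, params)
    c3d = delay_series(c3, params.T)
    return TimeSeries(c1.times, hill_effect(c3d.values, params),
                      "dimensionless", name="D")
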