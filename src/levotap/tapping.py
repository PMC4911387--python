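"""Alternate finger-tapping protocol driven by the basal-ganglia network.

The task is modelled as two actions in alternation: action 1 is the tap
(finger down, on either button), action 2 the lift-and-shift to the other
button.  The protocol cues action 1 (S = [+1, -1]: excitation of the cued
channel, inhibition of the rival), waits for the cued cortical activity to
reach the action threshold, and reverses the stimulus, repeating the cycle.
A physiological dead time (100 ms by default) is inserted after the first
selection to account for movement initiation and detection; steady-state
alternation is insensitive to it because the first cycle is discarded.

Tapping frequency counts tap-down (channel 1) threshold crossings per unit
time over the post-transient window, matching the clinical count of button
presses; a trial with no crossing yields frequency zero (fully blocked
movement at very low dopaminergic input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bg import BgNetwork, CONTRAST_SLOPE
from .params import BgParams, SynapticWeights

__all__ = ["TappingProtocol", "TappingResult", "run_tapping",
           "d_to_frequency_curve", "FrequencyCurve", "ACTION_THRESHOLD"]

#: Cortical activity level that triggers an action ("close to the maximum").
#: Calibrated once, together with the contrast-switch constants, so that the
#: protocol reproduces both published frequency anchors (2.89 Hz at D =
#: 0.55, 1.00 Hz at D = 0.22) with a single value.
ACTION_THRESHOLD = 0.80


@dataclass(frozen=True)
class TappingProtocol:
    """Protocol constants for the alternate tapping simulation."""

    action_threshold: float = ACTION_THRESHOLD
    physio_delay: float = 100.0       # [ms] dead time after the first action
    trial_duration: float = 15000.0   # [ms] hard cap on simulated time
    settle_duration: float = 1500.0   # [ms] pre-stimulus relaxation
    max_taps: int = 8                 # stop early after this many tap-downs
    dt: float = 1.0                   # [ms] Euler step

    def __post_init__(self) -> None:
        if not 0.5 < self.action_threshold < 1:
            raise ValueError("action_threshold must be in (0.5, 1)")
        if self.physio_delay < 0 or self.trial_duration <= 0:
            raise ValueError("invalid protocol timing")

    def stimulus(self, cued: int, n: int = 2) -> np.ndarray:
        """Bipolar cue: +1 for the cued channel, -1 for its rivals."""
        S = np.full(n, -1.0)
        S[cued] = 1.0
        return S


@dataclass(frozen=True)
class TappingResult:
    """Outcome of one tapping trial at fixed dopaminergic input."""

    D: float
    tap_times: np.ndarray        # [ms] channel-1 (tap-down) crossings
    all_crossings: tuple         # (time_ms, channel) for every selection
    cycle_times: np.ndarray      # [ms] tap-to-tap intervals, first discarded
    frequency_hz: float
    blocked: bool

    @property
    def frequency_tpm(self) -> float:
        return 60.0 * self.frequency_hz


def run_tapping(D: float, protocol: TappingProtocol = TappingProtocol(),
                params: BgParams = BgParams(),
                weights: SynapticWeights = SynapticWeights(),
                contrast_slope: float = CONTRAST_SLOPE,
                noise_rng: np.random.Generator | None = None,
                ) -> TappingResult:
    """Simulate the alternate tapping task at a fixed dopaminergic input.

    The network is settled at rest, then driven through stimulus reversals:
    each threshold crossing of the cued channel immediately hands the cue to
    the rival channel (the subject switches intention as soon as the action
    is released).  Frequency is the reciprocal mean tap-down interval after
    discarding the first, still transient, cycle.
    """
    if D < 0:
        raise ValueError("dopaminergic input D must be >= 0")
    net = BgNetwork(params, weights, contrast_slope)
    dt = protocol.dt
    net.settle(np.zeros(net.n), D, protocol.settle_duration, dt)

    cued = 0
    S = protocol.stimulus(cued, net.n)
    thr = protocol.action_threshold
    crossings: list[tuple[float, int]] = []
    hold_until = None   # physiological dead time after the first action
    prev = np.asarray(net.cortex, dtype=float).copy()
    t = 0.0
    n_steps = int(round(protocol.trial_duration / dt))
    n_downs = 0
    for _ in range(n_steps):
        net.step(S, D, dt, noise_rng)
        t += dt
        cort = np.asarray(net.cortex, dtype=float)
        if hold_until is None:
            c0, c1 = prev[cued], cort[cued]
            if c0 < thr <= c1:
                t_cross = t - dt + dt * (thr - c0) / (c1 - c0)
                crossings.append((t_cross, cued))
                if cued == 0:
                    n_downs += 1
                if len(crossings) == 1 and protocol.physio_delay > 0:
                    hold_until = t_cross + protocol.physio_delay
                else:
                    cued = 1 - cued
                    S = protocol.stimulus(cued, net.n)
        elif t >= hold_until:
            cued = 1 - cued
            S = protocol.stimulus(cued, net.n)
            hold_until = None
        prev = cort.copy()
        if n_downs >= protocol.max_taps:
            break

    tap_times = np.array([tc for tc, ch in crossings if ch == 0])
    if tap_times.size < 3:
        return TappingResult(D=D, tap_times=tap_times,
                             all_crossings=tuple(crossings),
                             cycle_times=np.array([]), frequency_hz=0.0,
                             blocked=True)
    cycles = np.diff(tap_times)[1:]   # first full cycle discarded
    freq = 1000.0 / float(np.mean(cycles))
    return TappingResult(D=D, tap_times=tap_times,
                         all_crossings=tuple(crossings),
                         cycle_times=cycles, frequency_hz=freq, blocked=False)


@dataclass(frozen=True)
class FrequencyCurve:
    """Precomputed mapping from dopaminergic input D to tapping frequency.

    Calling the curve interpolates linearly in taps/min and clamps outside
    the grid (end values held); ``out_of_range`` records whether any lookup
    was clamped.
    """

    D_grid: np.ndarray
    taps_per_min: np.ndarray
    clamp_events: list = field(default_factory=list, compare=False)

    def __call__(self, D) -> np.ndarray | float:
        D = np.asarray(D, dtype=float)
        lo, hi = self.D_grid[0], self.D_grid[-1]
        if np.any(D < lo) or np.any(D > hi):
            self.clamp_events.append(float(np.atleast_1d(D)[0]))
        v = np.interp(D, self.D_grid, self.taps_per_min)
        return float(v) if v.ndim == 0 else v

    def hz(self, D) -> np.ndarray | float:
        v = np.asarray(self(D)) / 60.0
        return float(v) if v.ndim == 0 else v


def d_to_frequency_curve(D_grid, protocol: TappingProtocol = TappingProtocol(),
                         params: BgParams = BgParams(),
                         weights: SynapticWeights = SynapticWeights(),
                         contrast_slope: float = CONTRAST_SLOPE,
                         ) -> FrequencyCurve:
    """Evaluate the tapping frequency on a grid of dopaminergic inputs.

    Each grid point is an independent deterministic simulation, so the curve
    is invariant to grid ordering and refinement.
    """
    D_grid = np.asarray(D_grid, dtype=float)
    if np.any(D_grid < 0) or np.any(D_grid > 1):
        raise ValueError("D grid must lie within [0, 1]")
    order = np.argsort(D_grid)
    tpm = np.empty_like(D_grid)
    for i in order:
        tpm[i] = run_tapping(float(D_grid[i]), protocol, params, weights,
                             contrast_slope).frequency_tpm
    return FrequencyCurve(D_grid=D_grid[order], taps_per_min=tpm[order])


def frequency_lookup(curve: FrequencyCurve, D) -> float:
    """Interpolate the precomputed curve at ``D`` (taps/min)."""
    return curve(D)
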