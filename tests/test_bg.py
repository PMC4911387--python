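"""Basal-ganglia network: unit nonlinearity, dopamine modulation, selection."""

import numpy as np
import pytest

from levotap.bg import BgNetwork, dopamine_drive, simulate_selection, \
    step_network, unit_response
from levotap.params import BgParams, SynapticWeights


class TestUnitResponse:
    def test_midpoint_and_saturation(self):
        p = BgParams()
        assert unit_response(p.u0, p) == pytest.approx(0.5)
        assert unit_response(50.0, p) == pytest.approx(1.0)
        assert unit_response(-50.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_published_slope_value(self):
        # a=4, u0=1: F(1.5) = 1/(1+e^-2)
        assert unit_response(1.5, BgParams()) == pytest.approx(0.8808, abs=1e-4)

    def test_monotone(self):
        u = np.linspace(-3, 5, 200)
        z = unit_response(u, BgParams())
        assert np.all(np.diff(z) > 0)


class TestDopamineDrive:
    def test_zero_dopamine_zero_terms(self):
        go, nogo, chi = dopamine_drive(0.0, [0.9, 0.1], [0.5, 0.0])
        np.testing.assert_array_equal(go, 0.0)
        assert nogo == 0.0 and chi == 0.0

    def test_contrast_sign_rule(self):
        """Strongly excited Go channels are potentiated, weakly excited
        ones suppressed; the magnitude never exceeds alpha*D."""
        p = BgParams()
        go, nogo, chi = dopamine_drive(0.55, [0.9, 0.1], [0.9, 0.1], p)
        assert go[0] > 0 > go[1]
        assert np.all(np.abs(go) <= p.alpha * 0.55)
        assert nogo == pytest.approx(p.beta * 0.55)
        assert chi == pytest.approx(p.gamma * 0.55)

    def test_raising_dopamine_disinhibits(self):
        """More dopamine: stronger NoGo inhibition and stronger suppression
        of the cholinergic interneuron (whose loss further favours Go)."""
        _, nogo_lo, chi_lo = dopamine_drive(0.22, [0.9, 0.1], [0.9, 0.1])
        _, nogo_hi, chi_hi = dopamine_drive(0.55, [0.9, 0.1], [0.9, 0.1])
        assert nogo_hi < nogo_lo < 0
        assert chi_hi < chi_lo < 0


class TestNetworkDynamics:
    def test_rest_state_suppresses_thalamus(self):
        """Without a stimulus the NoGo pathway prevails: GPi is active and
        the thalamus silent, so no action can start."""
        net = BgNetwork()
        net.settle(np.zeros(2), 0.22, 2000.0)
        acts = net.activities()
        assert np.all(acts["I"] > 0.9)
        assert np.all(acts["T"] < 0.01)
        assert np.all(acts["C"] < 0.1)

    def test_step_network_returns_activities_in_bounds(self):
        net = BgNetwork()
        acts = step_network(net, [1.0, -1.0], 0.4)
        for value in acts.values():
            assert np.all((np.asarray(value) >= 0) & (np.asarray(value) <= 1))

    def test_activities_bounded_through_selection(self):
        res = simulate_selection([1.0, -1.0], 0.55, 0.8, 5000.0)
        for trace in res.traces.values():
            assert trace.min() >= 0.0 and trace.max() <= 1.0

    def test_winner_takes_all_exclusivity(self):
        """At the selection instant exactly one cortical channel is above
        threshold and the rival is deeply suppressed."""
        res = simulate_selection([1.0, -1.0], 0.55, 0.8, 5000.0)
        assert res.winner == 0 and not res.timed_out
        final = res.traces["C"][-1]
        assert final[0] >= 0.8 > final[1]
        assert final[1] < 0.1

    def test_selection_time_monotone_in_dopamine(self):
        times = []
        for D in (0.25, 0.3, 0.4, 0.55):
            res = simulate_selection([1.0, -1.0], D, 0.8, 10000.0)
            assert not res.timed_out
            times.append(res.selection_time)
        assert all(t1 >= t2 for t1, t2 in zip(times, times[1:]))

    def test_blocked_at_very_low_dopamine(self):
        res = simulate_selection([1.0, -1.0], 0.1, 0.8, 4000.0)
        assert res.timed_out and res.selection_time is None

    def test_dt_halving_trajectory_convergence(self):
        def trajectory(dt):
            net = BgNetwork()
            for _ in range(int(1500 / dt)):
                net.step(np.zeros(2), 0.4, dt)
            S = np.array([1.0, -1.0])
            rec = int(round(1.0 / dt))
            out = []
            for k in range(int(1500 / dt)):
                net.step(S, 0.4, dt)
                if (k + 1) % rec == 0:
                    out.append(np.concatenate(
                        [np.atleast_1d(net.activity(p))
                         for p in net.POPULATIONS]))
            return np.array(out)

        diff = np.max(np.abs(trajectory(1.0) - trajectory(0.5)))
        assert diff < 1e-3

    def test_deterministic_without_noise(self):
        def run():
            net = BgNetwork()
            net.settle(np.zeros(2), 0.3, 500.0)
            for _ in range(500):
                net.step([1.0, -1.0], 0.3)
            return net.y.copy()

        np.testing.assert_array_equal(run(), run())

    def test_seeded_noise_reproducible_and_distinct(self):
        def run(seed):
            net = BgNetwork()
            rng = np.random.default_rng(seed)
            for _ in range(300):
                net.step([1.0, -1.0], 0.3, noise_rng=rng)
            return net.y.copy()

        np.testing.assert_array_equal(run(5), run(5))
        assert not np.array_equal(run(5), run(6))

    def test_coarse_step_rejected(self):
        net = BgNetwork()
        with pytest.raises(ValueError, match="too coarse"):
            net.step([0.0, 0.0], 0.3, dt=10.0)


class _AblatedNetwork(BgNetwork):
    """Network with the cholinergic interneuron silenced (activity ~ 0)."""

    def _rhs(self, y, S, D, noise):
        y = y.copy()
        y[6 * self.n + 1] = -1e3
        dy = super()._rhs(y, S, D, noise)
        dy[6 * self.n + 1] = 0.0
        return dy


class TestCholinergicSynergy:
    def test_ablation_shrinks_dopamine_sensitivity(self):
        """Dopamine alone is insufficient: clamping the cholinergic
        interneuron collapses the spread of selection times between the
        parkinsonian and healthy dopamine levels."""

        def spread(cls):
            times = {}
            for D in (0.22, 0.55):
                net = cls()
                net.reset()
                net.y[6 * net.n + 1] = -1e3 if cls is _AblatedNetwork else 0.0
                net.settle(np.zeros(2), D, 1500.0)
                res = simulate_selection([1.0, -1.0], D, 0.8, 15000.0,
                                         network=net)
                assert not res.timed_out
                times[D] = res.selection_time
            return abs(times[0.22] - times[0.55])

        assert spread(_AblatedNetwork) < spread(BgNetwork)


class TestWeightsValidation:
    def test_wrong_sign_rejected(self):
        with pytest.raises(ValueError, match="W_IG"):
            SynapticWeights(W_IG=np.eye(2) * 12.0)

    def test_default_dimensions_follow_channel_count(self):
        w = SynapticWeights(n_channels=3)
        assert w.W_CS.shape == (3, 3)
        assert w.W_STNE.shape == (3,)
        assert w.L[0, 1] == -1.2 and w.L[0, 0] == 0.0
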