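"""Unit tests for the integrate-and-fire network simulator."""

import numpy as np
import pytest

from neuromaxent.ifnet import (
    DELTA_U_REC_CRIT,
    DynamicsParams,
    NetworkTopology,
    NeuronState,
    advance_avalanche_step,
    apply_long_term_step,
    build_network,
    calibrate_delta_u_rec,
    delta_u_rec_for_state,
    pretrain,
    run_recording,
)

PARAMS = DynamicsParams(delta_u_rec=4.2e-3)


def chain_topology(g12: float = 0.6) -> NetworkTopology:
    """Two neurons, single excitatory synapse 0 -> 1."""
    return NetworkTopology(
        n_neurons=2, side=5.0,
        positions=np.zeros((2, 3)),
        is_inhibitory=np.zeros(2, dtype=bool),
        indptr=np.array([0, 1, 1], dtype=np.int64),
        targets=np.array([1], dtype=np.int32),
        strengths=np.array([g12]),
    )


class TestBuildNetwork:
    def test_inhibitory_fraction_and_geometry(self):
        topo = build_network(100, PARAMS, seed=0)
        assert topo.is_inhibitory.sum() == 20
        assert topo.side == pytest.approx((100 / 0.016) ** (1 / 3), rel=1e-12)
        assert topo.positions.shape == (100, 3)
        assert topo.positions.min() >= 0 and topo.positions.max() <= topo.side

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_degree_bounds_strengths_no_self_edges(self, seed):
        topo = build_network(100, PARAMS, seed=seed)
        deg = topo.out_degrees()
        assert deg.min() >= 2 and deg.max() <= 20
        assert topo.strengths.min() >= 0.4 and topo.strengths.max() <= 0.6
        for i in range(topo.n_neurons):
            tg, _ = topo.out_edges(i)
            assert i not in tg
            assert np.unique(tg).size == tg.size

    def test_determinism_and_too_small_network(self):
        a = build_network(30, PARAMS, seed=5)
        b = build_network(30, PARAMS, seed=5)
        np.testing.assert_array_equal(a.targets, b.targets)
        np.testing.assert_allclose(a.strengths, b.strengths)
        with pytest.raises(ValueError):
            build_network(1, PARAMS, seed=0)


class TestAvalancheStep:
    def test_excitatory_transmission(self):
        topo = chain_topology(0.5)
        st = NeuronState(np.array([1.0, 0.3]), np.ones(2), np.zeros(2, bool))
        new, fired = advance_avalanche_step(st, topo, PARAMS)
        assert list(fired) == [0]
        assert new.v[1] == pytest.approx(0.8)       # 0.3 + 1.0*1.0*0.5
        assert new.v[0] == 0.0
        assert new.u[0] == pytest.approx(0.95)      # depletion by 1 - 0.05
        assert new.refractory[0] and not new.refractory[1]

    def test_inhibitory_sign(self):
        topo = chain_topology(0.5)
        topo.is_inhibitory[0] = True
        st = NeuronState(np.array([1.0, 0.3]), np.ones(2), np.zeros(2, bool))
        new, _ = advance_avalanche_step(st, topo, PARAMS)
        assert new.v[1] == pytest.approx(-0.2)

    def test_refractory_neuron_does_not_fire(self):
        topo = chain_topology()
        st = NeuronState(np.array([1.0, 1.5]), np.ones(2), np.array([False, True]))
        _, fired = advance_avalanche_step(st, topo, PARAMS)
        assert list(fired) == [0]

    def test_no_firing_is_an_error(self):
        topo = chain_topology()
        st = NeuronState.resting(2)
        with pytest.raises(ValueError):
            advance_avalanche_step(st, topo, PARAMS)


class TestLongTermStep:
    def test_potentiation_is_beta_times_dv(self):
        g, total = apply_long_term_step(np.array([0.5]), np.array([0.5]), PARAMS)
        assert g[0] == pytest.approx(0.52)          # 0.04 * 0.5 = 0.02
        assert total == pytest.approx(0.02)

    def test_inactive_synapses_unchanged(self):
        g, total = apply_long_term_step(np.array([0.5, 0.4]), np.array([0.0, 0.0]), PARAMS)
        np.testing.assert_allclose(g, [0.5, 0.4])
        assert total == 0.0

    def test_normalized_depression_and_clipping(self):
        g, _ = apply_long_term_step(np.array([0.5, PARAMS.g_min]),
                                    np.array([0.5, 0.0]), PARAMS, normalize=True)
        assert g[0] == pytest.approx(0.5 + 0.02 - 0.01)
        assert g[1] == PARAMS.g_min                 # clipped at the floor


class TestRunRecording:
    def test_single_neuron_avalanche_in_chain(self):
        # 0.6 < vc at neuron 2: avalanche of S=1, D=1
        topo = chain_topology(0.6)
        st = NeuronState(np.array([1.0, 0.0]), np.ones(2), np.zeros(2, bool))
        res = run_recording(topo, PARAMS, n_avalanches=1, seed=0, state=st)
        assert res.catalog.size[0] == 1 and res.catalog.duration[0] == 1

    def test_precharged_chain_propagates(self):
        # neuron 2 pre-charged to 0.5: 0.5 + 0.6 >= 1 -> S=2, D=2
        topo = chain_topology(0.6)
        st = NeuronState(np.array([1.0, 0.5]), np.ones(2), np.zeros(2, bool))
        res = run_recording(topo, PARAMS, n_avalanches=1, seed=0, state=st)
        assert res.catalog.size[0] == 2 and res.catalog.duration[0] == 2

    def test_zero_budget_is_empty(self):
        topo = build_network(20, PARAMS, seed=0)
        res = run_recording(topo, PARAMS, n_timesteps=0, seed=0)
        assert len(res.events) == 0 and len(res.catalog) == 0

    def test_conservation_refractoriness_and_bounds(self):
        topo = build_network(30, DynamicsParams(delta_u_rec=6e-3), seed=1)
        res = run_recording(topo, DynamicsParams(delta_u_rec=6e-3),
                            n_timesteps=50_000, seed=2)
        # total spikes equal the summed avalanche sizes
        assert len(res.events) == res.catalog.size.sum()
        assert res.catalog.duration.sum() <= res.events.n_timesteps
        assert np.all(res.catalog.size >= 1) and np.all(res.catalog.duration >= 1)
        # refractory period: no neuron fires on consecutive timesteps
        for ch in range(30):
            t = res.events.times[res.events.channels == ch]
            if t.size > 1:
                assert np.diff(t).min() >= 2
        assert res.state.u.min() >= 0.0 and res.state.u.max() <= 1.0
        assert res.topology.strengths.min() >= PARAMS.g_min
        assert res.topology.strengths.max() <= 1.0

    def test_determinism(self):
        topo = build_network(25, PARAMS, seed=3)
        a = run_recording(topo, PARAMS, n_timesteps=20_000, seed=9)
        b = run_recording(topo, PARAMS, n_timesteps=20_000, seed=9)
        np.testing.assert_array_equal(a.events.times, b.events.times)
        np.testing.assert_array_equal(a.events.channels, b.events.channels)

    def test_participants_are_consistent(self):
        topo = build_network(25, PARAMS, seed=3)
        res = run_recording(topo, PARAMS, n_timesteps=20_000, seed=9,
                            record_participants=True)
        for a, part in enumerate(res.catalog.participants[:50]):
            assert part.size <= res.catalog.size[a]


class TestPretrain:
    def test_reshapes_strengths_and_is_deterministic(self):
        topo = build_network(30, DynamicsParams(delta_u_rec=8e-3), seed=4)
        t1 = pretrain(topo, DynamicsParams(delta_u_rec=8e-3), seed=5)
        t2 = pretrain(topo, DynamicsParams(delta_u_rec=8e-3), seed=5)
        np.testing.assert_allclose(t1.strengths, t2.strengths)
        # no longer uniform on [0.4, 0.6]
        assert t1.strengths.std() > 1.5 * topo.strengths.std()
        assert t1.strengths.min() < 0.4 or t1.strengths.max() > 0.6
        # original topology untouched
        assert topo.strengths.min() >= 0.4

    def test_zero_budget_is_identity(self):
        params = DynamicsParams(delta_u_rec=8e-3, pretrain_avalanches=0)
        topo = build_network(20, params, seed=4)
        assert pretrain(topo, params, seed=5) is topo


class TestCalibration:
    def test_state_table_lookup(self):
        crit = DELTA_U_REC_CRIT[100]
        assert delta_u_rec_for_state(100, "sub") == pytest.approx(0.1 * crit)
        assert delta_u_rec_for_state(100, "super") == pytest.approx(10 * crit)
        with pytest.raises(KeyError):
            delta_u_rec_for_state(33, "crit")

    def test_scan_finds_a_critical_plateau(self):
        # coarse scan at small N; estimate must label critical at 1x and
        # off-critical at 0.1x / 10x per the monotone contract
        res = calibrate_delta_u_rec(
            40, seed=1, grid=np.geomspace(3e-4, 3e-2, 7),
            n_avalanches=2000, refine=False)
        assert 1e-3 < res.estimate < 3e-2
        assert "critical" in res.labels
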