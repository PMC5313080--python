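import copy

import numpy as np
import pytest

from ca1net.builder import build_circuit
from ca1net.cells import fi_curve
from ca1net.config import load_config
from ca1net.engine import Network, network_clamp, simulate
from ca1net.perturb import mute_outputs
from tests.conftest import TOY_YAML


@pytest.fixture(scope="module")
def toy_net():
    cfg = load_config(TOY_YAML)
    positions, edges = build_circuit(cfg, seed=7)
    return Network(cfg, positions, edges)


def rekey(res):
    return np.sort(res.spike_gids * 10**9 + np.round(res.spike_times_ms * 40))


class TestSimulate:
    def test_zero_afferent_input_gives_silent_network(self, toy_net):
        cfg = copy.deepcopy(toy_net.cfg)
        for a in cfg.afferents.values():
            object.__setattr__(a, "rate_hz", 0.0)
        positions, edges = build_circuit(cfg, seed=7)
        res = simulate(Network(cfg, positions, edges), duration_ms=300.0, seed=1)
        assert res.spike_gids.size == 0

    def test_identical_seed_gives_identical_raster(self, toy_net):
        a = simulate(toy_net, duration_ms=300.0, seed=3)
        b = simulate(toy_net, duration_ms=300.0, seed=3)
        assert np.array_equal(rekey(a), rekey(b))
        assert a.config_digest == b.config_digest

    def test_different_seed_changes_raster(self, toy_net):
        a = simulate(toy_net, duration_ms=300.0, seed=3)
        b = simulate(toy_net, duration_ms=300.0, seed=4)
        assert not np.array_equal(rekey(a), rekey(b))

    def test_isolated_cell_rate_matches_fi_point(self, toy_net):
        # constant suprathreshold current into one unconnected cell matches
        # the single-cell characterization oracle
        cfg = copy.deepcopy(toy_net.cfg)
        for a in cfg.afferents.values():
            object.__setattr__(a, "rate_hz", 0.0)
        positions, edges = build_circuit(cfg, seed=7)
        net = Network(cfg, positions, edges)
        i_inj = np.zeros(net.n_local)
        i_inj[0] = 300.0
        res = simulate(net, duration_ms=1000.0, seed=1, i_inj_pa=i_inj)
        rate_net = res.spike_count() / 1.0
        rate_cell = fi_curve(cfg.neurons["E"], [300.0], duration_ms=1000.0)[0]
        assert rate_net == pytest.approx(rate_cell, rel=0.05)
        assert set(res.spike_gids) == {0}

    def test_spike_times_within_duration(self, toy_net):
        res = simulate(toy_net, duration_ms=300.0, seed=3)
        assert (res.spike_times_ms >= 0).all()
        assert (res.spike_times_ms <= 300.0).all()

    def test_dt_halving_changes_unconnected_counts_by_under_1pct(self):
        # afferent-driven, unconnected cells: integration accuracy check
        cfg = load_config(TOY_YAML.replace("rate_hz: 20.0", "rate_hz: 40.0"))
        proj = {k: v for k, v in cfg.budgets.items() if k[0] == "AFF"}
        from ca1net.config import SynapseBudgetMatrix
        cfg.budgets = SynapseBudgetMatrix(proj)
        positions, edges = build_circuit(cfg, seed=7)
        net = Network(cfg, positions, edges)
        n1 = simulate(net, duration_ms=1000.0, dt_ms=0.025, seed=2).spike_count()
        n2 = simulate(net, duration_ms=1000.0, dt_ms=0.0125, seed=2).spike_count()
        assert n1 > 100
        assert abs(n1 - n2) / n1 < 0.01

    def test_vm_and_current_recorders(self, toy_net):
        res = simulate(toy_net, duration_ms=200.0, seed=3,
                       record_vm_gids=[0, 1], record_current_gids=[0],
                       record_dt_ms=1.0)
        assert res.vm_mv.shape == (2, 200)
        assert res.current_pa.shape == (1, 200)
        assert np.isfinite(res.vm_mv).all()

    def test_nonpositive_dt_rejected(self, toy_net):
        with pytest.raises(ValueError):
            simulate(toy_net, duration_ms=10.0, dt_ms=0.0)


class TestMuting:
    def test_mute_fraction_zero_leaves_network_unchanged(self, toy_net):
        before = simulate(toy_net, duration_ms=300.0, seed=5)
        mute_outputs(toy_net, "E", 0.0, seed=5)
        after = simulate(toy_net, duration_ms=300.0, seed=5)
        toy_net.restore_weights()
        assert np.array_equal(rekey(before), rekey(after))

    def test_muting_is_reversible(self, toy_net):
        control = simulate(toy_net, duration_ms=300.0, seed=5)
        mute_outputs(toy_net, "E", 1.0, seed=5)
        muted = simulate(toy_net, duration_ms=300.0, seed=5)
        toy_net.restore_weights()
        restored = simulate(toy_net, duration_ms=300.0, seed=5)
        assert not np.array_equal(rekey(control), rekey(muted))
        assert np.array_equal(rekey(control), rekey(restored))

    def test_muted_weights_equal_structural_removal(self, toy_net):
        # zeroed outgoing weights are dynamically equivalent to deleting
        # the cells' outgoing edges
        mute_outputs(toy_net, "E", 1.0, seed=5)
        muted = simulate(toy_net, duration_ms=300.0, seed=5)
        toy_net.restore_weights()

        cfg = copy.deepcopy(toy_net.cfg)
        positions, edges = build_circuit(cfg, seed=7)
        net2 = Network(cfg, positions, edges)
        egids = net2.cells_of("E")
        net2.e_w[net2.edge_mask_from(egids)] = 0.0
        removed = simulate(net2, duration_ms=300.0, seed=5)
        assert np.array_equal(rekey(muted), rekey(removed))

    def test_unknown_population_rejected(self, toy_net):
        with pytest.raises(KeyError):
            mute_outputs(toy_net, "nope", 1.0)

    def test_partial_mute_selects_requested_fraction(self, toy_net):
        chosen = mute_outputs(toy_net, "E", 0.5, seed=5)
        toy_net.restore_weights()
        assert chosen.size == 30


class TestNetworkClamp:
    def test_silent_afferents_give_silent_cell(self, toy_net):
        res = network_clamp(toy_net, 0, afferent_spec={"AFF": 0.0, "E": 0.0,
                                                       "I": 0.0},
                            duration_ms=500.0, seed=1)
        assert res.spike_gids.size == 0

    def test_unknown_target_rejected(self, toy_net):
        with pytest.raises(KeyError):
            network_clamp(toy_net, 10**6)

    def test_rate_non_decreasing_with_afferent_weight(self, toy_net):
        counts = []
        for factor in (0.5, 1.0, 2.0):
            net = Network(toy_net.cfg, toy_net.positions, toy_net.edges)
            aff = net.cells_of("AFF")
            m = net.edge_mask_from(aff)
            net.e_w[m] *= factor
            res = network_clamp(net, 0, afferent_spec={"AFF": 30.0},
                                duration_ms=1000.0, seed=2)
            counts.append(res.spike_count())
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[-1] > 0

    def test_clamp_matches_full_run_with_others_muted(self, toy_net):
        """Clamping a cell out of the network reproduces its spike count in
        a full simulation where every other local cell is muted (both leave
        only the afferent drive intact)."""
        cfg = copy.deepcopy(toy_net.cfg)
        positions, edges = build_circuit(cfg, seed=7)
        net = Network(cfg, positions, edges)
        mute_outputs(net, "E", 1.0, seed=9)
        mute_outputs(net, "I", 1.0, seed=9)
        full = simulate(net, duration_ms=2000.0, seed=11)
        target = 0
        n_target_full = int((full.spike_gids == target).sum())

        net.restore_weights()
        clamp = network_clamp(net, target, afferent_spec={"AFF": cfg.afferents["AFF"].rate_hz,
                                                          "E": 0.0, "I": 0.0},
                              duration_ms=2000.0, seed=11)
        assert n_target_full > 10
        assert clamp.spike_count() == pytest.approx(n_target_full, rel=0.10)
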