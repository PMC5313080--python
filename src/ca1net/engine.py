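"""Clock-driven network simulation.

The engine integrates every cell as an adaptive exponential
integrate-and-fire neuron with double-exponential conductance synapses.  The
membrane uses a forward step at the fixed network time step; the synaptic
rise/decay states are updated exactly (they are pure exponentials between
events), so the per-step error comes from the membrane term only.  Spike
events are delivered with per-edge delays rounded to the nearest time step,
which makes replay deterministic for a given (configuration, seed, dt).

None of the model cells are spontaneously active: with silent afferents the
network is silent, and all activity is driven through the stimulating units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .builder import CellPositions, EdgeList, build_circuit, _rng_stream
from .config import NetworkConfig
from .stimulation import SpikeTrainSet, poisson_trains
from .synapses import norm_factor

_EXP_CLIP = 16.0


class SimulationError(RuntimeError):
    pass


@dataclass
class SimResult:
    spike_gids: np.ndarray
    spike_times_ms: np.ndarray
    populations: dict[str, slice]
    dt_ms: float
    duration_ms: float
    seed: int
    config_digest: str
    record_dt_ms: float | None = None
    vm_gids: np.ndarray | None = None
    vm_mv: np.ndarray | None = None          # (len(vm_gids), n_samples)
    current_gids: np.ndarray | None = None
    current_pa: np.ndarray | None = None     # (len(current_gids), n_samples)

    def raster_of(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        s = self.populations[population]
        m = (self.spike_gids >= s.start) & (self.spike_gids < s.stop)
        return self.spike_gids[m], self.spike_times_ms[m]

    def spike_count(self, population: str | None = None) -> int:
        if population is None:
            return int(self.spike_gids.size)
        return int(self.raster_of(population)[0].size)


class Network:
    """A built, simulation-ready network (positions + compiled edges)."""

    def __init__(self, cfg: NetworkConfig, positions: CellPositions,
                 edges: EdgeList):
        self.cfg = cfg
        self.positions = positions
        self.edges = edges
        self.n_local = sum(t.count for t in cfg.cell_types.values())
        self.n_sources = positions.n_cells  # local cells + afferent units

        # per-cell neuron parameter arrays
        names, params = list(cfg.cell_types), []
        self.channel_names = list(cfg.channels)
        ch_index = {n: i for i, n in enumerate(self.channel_names)}
        per_cell = {k: np.empty(self.n_local) for k in
                    ("e_l", "g_l", "c", "v_t", "d_t", "v_reset", "t_ref",
                     "a", "b", "tau_w", "v_spike")}
        for name in names:
            sl = positions.slices[name]
            p = cfg.neurons[cfg.cell_types[name].neuron_params_ref]
            for k, v in (("e_l", p.e_leak_mv), ("g_l", p.g_leak_ns),
                         ("c", p.c_pf), ("v_t", p.v_thresh_mv),
                         ("d_t", p.delta_t_mv), ("v_reset", p.v_reset_mv),
                         ("t_ref", p.t_ref_ms), ("a", p.adapt_a_ns),
                         ("b", p.adapt_b_pa), ("tau_w", p.tau_w_ms),
                         ("v_spike", p.v_spike_mv)):
                per_cell[k][sl] = v
        self.cell = per_cell
        del params

        # compile edges: mixed GABA-A,B projections contribute a second
        # (GABA-B) edge per connection
        pre, post, ch, w, delay = [], [], [], [], []
        if len(edges):
            labels = edges.pair_labels
            base_ch = np.empty(len(edges), dtype=np.int64)
            gabab_ratio = np.zeros(len(edges))
            for lab in np.unique(labels):
                p_, q_ = lab.split("->")
                proj = cfg.budgets[(p_, q_)]
                m = labels == lab
                base_ch[m] = ch_index[proj.channel]
                if proj.is_mixed and proj.weight_ns > 0:
                    gabab_ratio[m] = proj.gabab_weight_ns / proj.weight_ns
            pre.append(edges.pre_gid)
            post.append(edges.post_gid)
            ch.append(base_ch)
            w.append(edges.weight.astype(float))
            delay.append(edges.delay_ms)
            mixed = gabab_ratio > 0
            if mixed.any():
                pre.append(edges.pre_gid[mixed])
                post.append(edges.post_gid[mixed])
                ch.append(np.full(mixed.sum(), ch_index["GABAB"], dtype=np.int64))
                w.append(edges.weight[mixed] * gabab_ratio[mixed])
                delay.append(edges.delay_ms[mixed])
        self.e_pre = np.concatenate(pre) if pre else np.empty(0, np.int64)
        self.e_post = np.concatenate(post) if post else np.empty(0, np.int64)
        self.e_ch = np.concatenate(ch) if ch else np.empty(0, np.int64)
        self.e_w = np.concatenate(w) if w else np.empty(0)
        self.e_delay = np.concatenate(delay) if delay else np.empty(0)

        order = np.argsort(self.e_pre, kind="stable")
        for name in ("e_pre", "e_post", "e_ch", "e_w", "e_delay"):
            setattr(self, name, getattr(self, name)[order])
        self.csr = np.searchsorted(self.e_pre, np.arange(self.n_sources + 1))
        self.base_w = self.e_w.copy()

        self.ch_tau1 = np.array([cfg.channels[n].tau1_ms for n in self.channel_names])
        self.ch_tau2 = np.array([cfg.channels[n].tau2_ms for n in self.channel_names])
        self.ch_erev = np.array([cfg.channels[n].e_rev_mv for n in self.channel_names])
        self.ch_norm = np.array([norm_factor(t1, t2)
                                 for t1, t2 in zip(self.ch_tau1, self.ch_tau2)])

    # -- perturbation support -------------------------------------------------
    def cells_of(self, population: str) -> np.ndarray:
        return self.positions.gids_of(population)

    def edge_mask_from(self, gids: np.ndarray) -> np.ndarray:
        sel = np.zeros(self.n_sources, dtype=bool)
        sel[gids] = True
        return sel[self.e_pre]

    def restore_weights(self):
        self.e_w = self.base_w.copy()

    def type_of_gid(self, gid: int) -> str:
        for name, sl in self.positions.slices.items():
            if sl.start <= gid < sl.stop:
                return name
        raise KeyError(f"unknown id {gid}")


def build_network(cfg: NetworkConfig, seed: int | None = None) -> Network:
    positions, edges = build_circuit(cfg, seed)
    return Network(cfg, positions, edges)


def _stim_events(net: Network, stim: dict[str, SpikeTrainSet] | None,
                 duration_ms: float, dt_ms: float, seed: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(step, source gid) arrays for all afferent spikes, step-sorted.

    With ``stim=None``, Poisson trains are generated for every afferent
    population at its configured rate, on named seed streams.
    """
    cfg = net.cfg
    gids, steps = [], []
    for name, aff in cfg.afferents.items():
        if stim is not None and name in stim:
            trains = stim[name]
        elif stim is None:
            sub = _rng_stream(seed, f"stim:{name}")
            trains = poisson_trains(aff.count, aff.rate_hz, duration_ms,
                                    int(sub.integers(2**31)))
        else:
            continue
        unit_gid, t = trains.as_raster()
        base = net.positions.slices[name].start
        keep = t < duration_ms
        gids.append(unit_gid[keep] + base)
        steps.append(np.floor(t[keep] / dt_ms).astype(np.int64))
    if not gids:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    g = np.concatenate(gids)
    s = np.concatenate(steps)
    order = np.argsort(s, kind="stable")
    return s[order], g[order]


def simulate(net: Network, duration_ms: float = 2000.0, dt_ms: float = 0.025,
             stim: dict[str, SpikeTrainSet] | None = None,
             seed: int = 0,
             record_vm_gids=None,
             record_current_gids=None,
             record_dt_ms: float = 1.0,
             extra_events: tuple[np.ndarray, np.ndarray] | None = None,
             i_inj_pa: dict[str, float] | np.ndarray | None = None
             ) -> SimResult:
    """Integrate the network and return the spike raster (plus recordings).

    ``record_current_gids`` records each cell's net synaptic membrane current,
    the quantity fed to the extracellular-potential proxy.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    n = net.n_local
    n_steps = int(round(duration_ms / dt_ms))
    cell = net.cell
    e_l, g_l, c = cell["e_l"], cell["g_l"], cell["c"]
    v_t, d_t, v_reset = cell["v_t"], cell["d_t"], cell["v_reset"]
    a, b, tau_w = cell["a"], cell["b"], cell["tau_w"]
    v_spike = cell["v_spike"]
    ref_steps = np.round(cell["t_ref"] / dt_ms).astype(np.int64)

    n_ch = len(net.channel_names)
    dec1 = np.exp(-dt_ms / net.ch_tau1)[:, None]
    dec2 = np.exp(-dt_ms / net.ch_tau2)[:, None]
    erev = net.ch_erev[:, None]

    delay_steps = np.maximum(1, np.round(net.e_delay / dt_ms).astype(np.int64))
    d_max = int(delay_steps.max()) + 1 if delay_steps.size else 1
    pending: list[list] = [[] for _ in range(d_max)]
    w_inc = net.e_w * net.ch_norm[net.e_ch]

    if i_inj_pa is None:
        i_ext = 0.0
    elif isinstance(i_inj_pa, dict):
        i_ext = np.zeros(n)
        for pop, amp in i_inj_pa.items():
            i_ext[net.positions.slices[pop]] = amp
    else:
        i_ext = np.asarray(i_inj_pa, dtype=float)

    ev_step, ev_gid = _stim_events(net, stim, duration_ms, dt_ms, seed)
    if extra_events is not None:
        es, eg = extra_events
        ev_step = np.concatenate([ev_step, es])
        ev_gid = np.concatenate([ev_gid, eg])
        order = np.argsort(ev_step, kind="stable")
        ev_step, ev_gid = ev_step[order], ev_gid[order]
    ev_ptr = 0

    rec_every = max(1, int(round(record_dt_ms / dt_ms)))
    vm_gids = np.asarray(record_vm_gids, dtype=np.int64) if record_vm_gids is not None else None
    cur_gids = np.asarray(record_current_gids, dtype=np.int64) if record_current_gids is not None else None
    n_samp = n_steps // rec_every
    vm_buf = np.empty((vm_gids.size, n_samp)) if vm_gids is not None else None
    cur_buf = np.empty((cur_gids.size, n_samp)) if cur_gids is not None else None

    v = e_l.copy()
    w = np.zeros(n)
    A = np.zeros((n_ch, n))
    B = np.zeros((n_ch, n))
    ref = np.zeros(n, dtype=np.int64)
    out_gid, out_t = [], []
    csr = net.csr
    samp = 0

    for k in range(n_steps):
        slot = k % d_max
        if pending[slot]:
            for ch_i, post_i, w_i in pending[slot]:
                np.add.at(A, (ch_i, post_i), w_i)
                np.add.at(B, (ch_i, post_i), w_i)
            pending[slot] = []
        A *= dec1
        B *= dec2
        g = B - A
        i_syn = ((erev - v) * g).sum(axis=0)

        active = ref <= 0
        expo = np.zeros(n)
        nz = d_t > 0
        expo[nz] = g_l[nz] * d_t[nz] * np.exp(
            np.minimum((v[nz] - v_t[nz]) / d_t[nz], _EXP_CLIP))
        dv = (-g_l * (v - e_l) + expo - w + i_syn + i_ext) / c
        v = np.where(active, v + dt_ms * dv, v)
        w += dt_ms * (a * (v - e_l) - w) / tau_w
        ref -= 1

        spk = active & ((v >= v_spike) | ((d_t == 0) & (v >= v_t)))
        if spk.any():
            idx = np.nonzero(spk)[0]
            if not np.isfinite(v[idx]).all():
                bad = idx[~np.isfinite(v[idx])][0]
                raise SimulationError(f"voltage diverged at cell {bad}")
            out_gid.append(idx)
            out_t.append(np.full(idx.size, (k + 1) * dt_ms))
            v[idx] = v_reset[idx]
            w[idx] += b[idx]
            ref[idx] = ref_steps[idx]
        if not np.isfinite(v).all():
            raise SimulationError(
                f"voltage diverged at cell {int(np.nonzero(~np.isfinite(v))[0][0])}")

        # gather spiking sources for event scatter (local + afferent)
        srcs = out_gid[-1] if spk.any() else None
        if ev_ptr < ev_step.size and ev_step[ev_ptr] == k:
            j = np.searchsorted(ev_step, k, side="right")
            aff = ev_gid[ev_ptr:j]
            srcs = aff if srcs is None else np.concatenate([srcs, aff])
            ev_ptr = j
        if srcs is not None and srcs.size:
            starts, stops = csr[srcs], csr[srcs + 1]
            total = int((stops - starts).sum())
            if total:
                eidx = np.concatenate(
                    [np.arange(s0, s1) for s0, s1 in zip(starts, stops)
                     if s1 > s0])
                tgt = (k + delay_steps[eidx]) % d_max
                for slot_v in np.unique(tgt):
                    m = tgt == slot_v
                    pending[slot_v].append(
                        (net.e_ch[eidx[m]], net.e_post[eidx[m]], w_inc[eidx[m]]))

        if (k + 1) % rec_every == 0 and samp < n_samp:
            if vm_buf is not None:
                vm_buf[:, samp] = v[vm_gids]
            if cur_buf is not None:
                cur_buf[:, samp] = i_syn[cur_gids]
            samp += 1

    gids = np.concatenate(out_gid) if out_gid else np.empty(0, np.int64)
    ts = np.concatenate(out_t) if out_t else np.empty(0)
    return SimResult(
        spike_gids=gids, spike_times_ms=ts,
        populations=dict(net.positions.slices) if net.positions is not None else {},
        dt_ms=dt_ms, duration_ms=duration_ms, seed=seed,
        config_digest=net.cfg.digest(),
        record_dt_ms=record_dt_ms if (vm_buf is not None or cur_buf is not None) else None,
        vm_gids=vm_gids, vm_mv=vm_buf,
        current_gids=cur_gids, current_pa=cur_buf,
    )


def network_clamp(net: Network, target_gid: int,
                  afferent_spec: dict[str, object] | None = None,
                  duration_ms: float = 2000.0, dt_ms: float = 0.025,
                  seed: int = 0, record_vm: bool = False) -> SimResult:
    """Simulate a single cell extracted from the network.

    All afferent synapses onto the target stay intact; every presynaptic
    source is replaced by a prescribed spike train.  ``afferent_spec`` maps a
    population name to either a rate in Hz (independent Poisson trains per
    presynaptic source of that population) or a :class:`SpikeTrainSet` with
    one train per presynaptic source.  Unlisted afferent populations default
    to their configured rate; unlisted local populations are silent.
    """
    if not (0 <= target_gid < net.n_local):
        raise KeyError(f"unknown id {target_gid}")
    spec = dict(afferent_spec or {})
    for name, aff in net.cfg.afferents.items():
        spec.setdefault(name, aff.rate_hz)

    incoming = np.nonzero(net.e_post == target_gid)[0]
    pre_sources = net.e_pre[incoming]

    # single-cell sub-network sharing the target's parameters
    sub = object.__new__(Network)
    sub.cfg = net.cfg
    sub.n_local = 1
    sub.channel_names = net.channel_names
    sub.ch_tau1, sub.ch_tau2 = net.ch_tau1, net.ch_tau2
    sub.ch_erev, sub.ch_norm = net.ch_erev, net.ch_norm
    sub.cell = {k: np.array([vals[target_gid]]) for k, vals in net.cell.items()}
    uniq, inv = np.unique(pre_sources, return_inverse=True)
    sub.n_sources = uniq.size
    sub.e_pre = inv.astype(np.int64)
    sub.e_post = np.zeros(incoming.size, dtype=np.int64)
    sub.e_ch = net.e_ch[incoming]
    sub.e_w = net.e_w[incoming]
    sub.e_delay = net.e_delay[incoming]
    order = np.argsort(sub.e_pre, kind="stable")
    for nm in ("e_pre", "e_post", "e_ch", "e_w", "e_delay"):
        setattr(sub, nm, getattr(sub, nm)[order])
    sub.csr = np.searchsorted(sub.e_pre, np.arange(sub.n_sources + 1))
    sub.base_w = sub.e_w.copy()
    sub.positions = None

    # prescribed trains per unique presynaptic source
    steps, gl = [], []
    rng = _rng_stream(seed, f"clamp:{target_gid}")
    for j, src in enumerate(uniq):
        pop = net.type_of_gid(int(src))
        entry = spec.get(pop)
        if entry is None:
            continue
        if isinstance(entry, SpikeTrainSet):
            local_i = int(src - net.positions.slices[pop].start)
            t = entry.trains[local_i % entry.n_units]
        else:
            rate = float(entry)
            t = poisson_trains(1, rate, duration_ms,
                               int(rng.integers(2**31))).trains[0]
        if t.size:
            steps.append(np.floor(t / dt_ms).astype(np.int64))
            gl.append(np.full(t.size, j, dtype=np.int64))
    if steps:
        es = np.concatenate(steps)
        eg = np.concatenate(gl)
        o = np.argsort(es, kind="stable")
        events = (es[o], eg[o])
    else:
        events = (np.empty(0, np.int64), np.empty(0, np.int64))

    res = simulate(sub, duration_ms, dt_ms, stim={}, seed=seed,
                   record_vm_gids=[0] if record_vm else None,
                   extra_events=events)
    res.populations = {net.type_of_gid(target_gid): slice(0, 1)}
    return res
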