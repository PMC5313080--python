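"""Perturbation operators: muting, budget scaling, interneuron
homogenization, and GABA-B removal with charge-matched GABA-A compensation.

Weight-level perturbations (muting, GABA-B manipulation) act on a built
network without touching placement or the per-projection RNG streams, so the
unperturbed projections stay byte-identical to the control run.  Structural
perturbations (pyramidal-recurrence scaling, the staged interneuron morph)
are plain configuration transforms: each stage is an ordinary network
configuration that is then rebuilt.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from .builder import _rng_stream
from .config import NetworkConfig, Projection
from .engine import Network
from .synapses import SynapseParams, charge_match_scale

KINDS = ("mute_outputs", "mute_fraction", "remove_gabab",
         "charge_matched_gabaa", "homogenize_interneurons", "scale_pyr_pyr")

MORPH_STAGES = ("ephys", "input_weights", "input_numbers", "full")

# broad molecular classes used in the partial-muting experiments
PV_CLASS = ("PVB", "Bis", "Axo")
SOM_CLASS = ("OLM", "Bis")


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str
    targets: tuple[str, ...] = ()
    fraction: float = 1.0
    factor: float = 1.0          # scale_pyr_pyr multiplier
    stage: str = "full"          # homogenization stage
    donor: str = "PVB"           # homogenization donor type

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")
        if self.kind == "homogenize_interneurons" and self.stage not in MORPH_STAGES:
            raise ValueError(f"unknown morph stage {self.stage!r}")


def mute_outputs(net: Network, population: str, fraction: float = 1.0,
                 seed: int = 0) -> np.ndarray:
    """Zero the outgoing weights of a (fraction of a) population.

    Returns the muted gids.  Cell selection uses its own named RNG stream so
    repeated experiments mute the same cells for the same seed.
    """
    if population not in net.positions.slices:
        raise KeyError(f"unknown target type {population!r}")
    gids = net.cells_of(population)
    if fraction >= 1.0:
        chosen = gids
    elif fraction <= 0.0:
        chosen = gids[:0]
    else:
        rng = _rng_stream(seed, f"perturb:mute:{population}")
        k = int(round(fraction * gids.size))
        chosen = rng.choice(gids, size=k, replace=False)
    net.e_w[net.edge_mask_from(chosen)] = 0.0
    return chosen


def _ngf_gabab_mask(net: Network) -> np.ndarray:
    ngf = net.cells_of("NGF")
    ch_b = net.channel_names.index("GABAB")
    return net.edge_mask_from(ngf) & (net.e_ch == ch_b)


def remove_gabab(net: Network):
    """Zero the GABA-B component of all neurogliaform output synapses."""
    net.e_w[_ngf_gabab_mask(net)] = 0.0


def charge_matched_gabaa(net: Network) -> float:
    """Remove the GABA-B component and rescale the neurogliaform GABA-A
    conductance so each output synapse transfers the same total charge as the
    control mixed synapse.  Returns the applied scale factor (the GABA-A
    conductance grows by 1 + k*g_B/g_A)."""
    cfg = net.cfg
    proj = cfg.budgets[("NGF", "Pyr")]
    ga = SynapseParams.from_channel(cfg.channels[proj.channel], proj.weight_ns)
    gb = SynapseParams.from_channel(cfg.channels["GABAB"], proj.gabab_weight_ns)
    k = charge_match_scale(replace(ga, g_max_ns=1.0), replace(gb, g_max_ns=1.0))
    remove_gabab(net)
    ngf = net.cells_of("NGF")
    ch_a = net.channel_names.index(cfg.budgets[("NGF", "Pyr")].channel)
    m = net.edge_mask_from(ngf) & (net.e_ch == ch_a)
    ratio = proj.gabab_weight_ns / proj.weight_ns
    net.e_w[m] *= 1.0 + k * ratio
    return k * ratio


def scale_pyr_pyr(cfg: NetworkConfig, factor: float) -> NetworkConfig:
    """Multiply the pyramidal-to-pyramidal synapse budget (0 removes the
    recurrent collaterals entirely; 0.5 and 2 halve / double them)."""
    out = copy.deepcopy(cfg)
    key = None
    for pre in cfg.principal_types:
        if (pre, pre) in cfg.budgets:
            key = (pre, pre)
    if key is None:
        raise KeyError("no principal-to-principal projection declared")
    out.budgets = out.budgets.replace(key, synapses=cfg.budgets[key].synapses * factor)
    return out


def homogenize_interneurons(cfg: NetworkConfig, stage: str = "full",
                            donor: str = "PVB") -> NetworkConfig:
    """Staged interneuron morph toward a single donor type.

    ``ephys``: all interneurons take the donor's electrophysiological profile.
    ``input_weights``: additionally, synapses onto interneurons take the
    weight and kinetics of the corresponding synapse onto the donor.
    ``input_numbers``: additionally, per-cell input synapse numbers onto each
    interneuron type match the donor's (budgets rescaled by cell count).
    ``full``: additionally, outgoing synapse numbers, weights and kinetics
    are the donor's, completing the conversion.
    """
    if stage not in MORPH_STAGES:
        raise ValueError(f"unknown morph stage {stage!r}")
    out = copy.deepcopy(cfg)
    inters = [n for n in cfg.interneuron_types]
    order = MORPH_STAGES.index(stage)

    out.cell_types = {
        n: (replace(t, neuron_params_ref=donor) if n in inters else t)
        for n, t in out.cell_types.items()
    }
    if order < 1:
        return out

    proj = dict(out.budgets.items())
    n_of = {p: cfg.population_count(p) for p in cfg.populations}

    def set_proj(key, p):
        proj[key] = p

    for (pre, post), p in list(proj.items()):
        if post in inters and post != donor and (pre, donor) in cfg.budgets:
            ref = cfg.budgets[(pre, donor)]
            new = replace(p, weight_ns=ref.weight_ns, channel=ref.channel,
                          gabab_weight_ns=ref.gabab_weight_ns)
            if order >= 2 and n_of[donor] > 0:
                # per-cell convergence copied from the donor
                new = replace(new, synapses=ref.synapses / n_of[donor] * n_of[post],
                              syn_per_conn=ref.syn_per_conn)
            set_proj((pre, post), new)
    if order >= 3:
        for t in inters:
            if t == donor:
                continue
            # outgoing projections become donor-typed
            for (pre, post), p in list(proj.items()):
                if pre != t:
                    continue
                ref = cfg.budgets.items() and cfg.budgets[(donor, post)] \
                    if (donor, post) in cfg.budgets else None
                if ref is None:
                    proj[(pre, post)] = replace(p, synapses=0.0)
                else:
                    proj[(pre, post)] = replace(
                        p, synapses=ref.synapses / n_of[donor] * n_of[t],
                        syn_per_conn=ref.syn_per_conn, weight_ns=ref.weight_ns,
                        channel=ref.channel, gabab_weight_ns=ref.gabab_weight_ns,
                        zones=ref.zones)
        out.profiles = {**out.profiles,
                        **{t: cfg.profiles[donor] for t in inters}}
    from .config import SynapseBudgetMatrix
    out.budgets = SynapseBudgetMatrix(proj)
    return out


def apply_perturbation(target, spec: PerturbationSpec, seed: int = 0):
    """Apply a perturbation to a built network (weight-level kinds) or a
    configuration (structural kinds).  Returns the perturbed object."""
    if spec.kind in ("mute_outputs", "mute_fraction"):
        if not isinstance(target, Network):
            raise TypeError("muting acts on a built network")
        for pop in spec.targets:
            mute_outputs(target, pop, spec.fraction, seed)
        return target
    if spec.kind == "remove_gabab":
        remove_gabab(target)
        return target
    if spec.kind == "charge_matched_gabaa":
        charge_matched_gabaa(target)
        return target
    if spec.kind == "scale_pyr_pyr":
        if isinstance(target, Network):
            raise TypeError("budget scaling acts on a configuration")
        return scale_pyr_pyr(target, spec.factor)
    if spec.kind == "homogenize_interneurons":
        return homogenize_interneurons(target, spec.stage, spec.donor)
    raise ValueError(spec.kind)
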