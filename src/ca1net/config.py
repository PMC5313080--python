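"""Network configuration: loading, validation, census, and rescaling.

The configuration is a key-value tree (YAML) describing the cell-type census,
the laminar prism geometry, the per-type-pair synapse budgets, axonal bouton
distance profiles, afferent (CA3 / entorhinal layer III) drive, synaptic
channel kinetics, and the reduced single-compartment neuron parameters.  The
packaged full-scale configuration describes the rat CA1 area: 311,500
pyramidal cells, eight interneuron classes totalling 27,240 cells, and
454,700 Poisson stimulating units standing in for CA3 and ECIII afferents.

Geometric dimensions, axonal Gaussian parameters, synaptic conductances and
GABA-B kinetics are documented estimates (they are constrained by anatomy
only indirectly) and are fully configurable; the census and synapse budgets
are data.
"""

from __future__ import annotations

import copy
import hashlib
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

LAYERS = ("SO", "SP", "SR", "SLM")

ZONES = (
    "AIS",
    "soma",
    "proximal_dendrite_SO",
    "proximal_dendrite_SR",
    "distal_dendrite_SLM",
    "basal_dendrite",
)

SCALING_MODES = ("preserve_convergence", "preserve_probability")


class ConfigError(ValueError):
    """Raised when a configuration fails validation; names the offending key."""


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    count: int
    layer: str
    is_principal: bool
    neuron_params_ref: str


@dataclass(frozen=True)
class LayerGeometry:
    """Prism extents (um) and stacked, non-overlapping layer height bounds."""

    longitudinal_um: float
    transverse_um: float
    layers: Mapping[str, tuple[float, float]]

    @property
    def height_um(self) -> float:
        return max(hi for _, hi in self.layers.values())

    def layer_bounds(self, layer: str) -> tuple[float, float]:
        return self.layers[layer]


@dataclass(frozen=True)
class AxonalProfile:
    """Gaussian bouton-distance profile of one presynaptic type (um)."""

    mean_um: float
    sd_um: float
    extent_um: float
    bin_um: float = 100.0


@dataclass(frozen=True)
class SynapseChannel:
    """Double-exponential conductance kinetics shared by a family of synapses."""

    name: str
    tau1_ms: float
    tau2_ms: float
    e_rev_mv: float


@dataclass(frozen=True)
class Projection:
    """Synapse budget and per-connection parameters for one (pre, post) pair."""

    pre: str
    post: str
    synapses: float            # total synapse count (full matrix entry)
    syn_per_conn: int          # synapses per connection, 1..10
    weight_ns: float           # peak conductance per synapse (nS)
    channel: str
    zones: tuple[str, ...]
    gabab_weight_ns: float = 0.0   # mixed GABA-A,B synapses carry a second component

    @property
    def is_mixed(self) -> bool:
        return self.gabab_weight_ns > 0.0


class SynapseBudgetMatrix:
    """All pairwise synapse budgets, keyed by (pre type, post type)."""

    def __init__(self, projections: Mapping[tuple[str, str], Projection]):
        self._proj = dict(projections)

    def __getitem__(self, key: tuple[str, str]) -> Projection:
        return self._proj[key]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._proj

    def items(self):
        return self._proj.items()

    def pairs(self) -> list[tuple[str, str]]:
        return list(self._proj)

    def total_synapses(self) -> float:
        return float(sum(p.synapses for p in self._proj.values()))

    def replace(self, key, **kw) -> "SynapseBudgetMatrix":
        proj = dict(self._proj)
        proj[key] = replace(proj[key], **kw)
        return SynapseBudgetMatrix(proj)

    def map(self, fn) -> "SynapseBudgetMatrix":
        return SynapseBudgetMatrix({k: fn(p) for k, p in self._proj.items()})


@dataclass(frozen=True)
class AfferentSpec:
    name: str
    count: int
    rate_hz: float
    layer: str


@dataclass(frozen=True)
class NeuronParams:
    """Adaptive exponential integrate-and-fire parameters (mV, ms, MOhm, pA)."""

    e_leak_mv: float
    r_in_mohm: float
    tau_m_ms: float
    v_thresh_mv: float         # exponential take-off potential V_T
    delta_t_mv: float          # spike sharpness; 0 gives a hard threshold
    v_reset_mv: float
    t_ref_ms: float
    adapt_a_ns: float = 0.0    # subthreshold adaptation conductance
    adapt_b_pa: float = 0.0    # spike-triggered adaptation increment
    tau_w_ms: float = 100.0

    @property
    def g_leak_ns(self) -> float:
        return 1000.0 / self.r_in_mohm

    @property
    def c_pf(self) -> float:
        return self.tau_m_ms * self.g_leak_ns

    @property
    def v_spike_mv(self) -> float:
        """Numerical spike-detection cutoff above the take-off potential."""
        return self.v_thresh_mv + max(15.0, 5.0 * self.delta_t_mv)


@dataclass
class NetworkConfig:
    name: str
    seed: int
    cell_types: dict[str, CellTypeSpec]
    geometry: LayerGeometry
    budgets: SynapseBudgetMatrix
    profiles: dict[str, AxonalProfile]
    afferents: dict[str, AfferentSpec]
    channels: dict[str, SynapseChannel]
    neurons: dict[str, NeuronParams]
    ephys_targets: dict[str, dict[str, float]] = field(default_factory=dict)
    sweep_protocols: dict[str, dict[str, float]] = field(default_factory=dict)
    scale_fraction: float = 1.0
    scale_mode: str | None = None
    conduction_velocity_um_per_ms: float = 300.0
    delay_offset_ms: float = 0.5

    @property
    def principal_types(self) -> list[str]:
        return [n for n, t in self.cell_types.items() if t.is_principal]

    @property
    def interneuron_types(self) -> list[str]:
        return [n for n, t in self.cell_types.items() if not t.is_principal]

    @property
    def populations(self) -> list[str]:
        """Local cell types followed by afferent populations."""
        return list(self.cell_types) + list(self.afferents)

    def population_count(self, name: str) -> int:
        if name in self.cell_types:
            return self.cell_types[name].count
        return self.afferents[name].count

    def digest(self) -> str:
        """Stable content hash of the full parameterization."""
        blob = yaml.safe_dump(config_to_dict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class CensusReport:
    total: int
    principal: int
    interneurons: int
    afferent_units: int
    per_type: dict[str, int]


# ---------------------------------------------------------------------------
# Parsing and validation
# ---------------------------------------------------------------------------

def _require(cond: bool, msg: str):
    if not cond:
        raise ConfigError(msg)


def config_from_dict(doc: dict) -> NetworkConfig:
    _require(isinstance(doc, dict) and "cell_types" in doc, "missing key: cell_types")
    raw_types = doc["cell_types"] or {}
    _require(len(raw_types) > 0, "cell_types: configuration declares zero cell types")

    cell_types: dict[str, CellTypeSpec] = {}
    for name, t in raw_types.items():
        count = int(t["count"])
        _require(count >= 0, f"cell_types.{name}.count: negative count {count}")
        layer = t["layer"]
        _require(layer in LAYERS, f"cell_types.{name}.layer: unknown layer {layer!r}")
        cell_types[name] = CellTypeSpec(
            name=name,
            count=count,
            layer=layer,
            is_principal=bool(t.get("is_principal", False)),
            neuron_params_ref=t.get("neuron", name),
        )

    geo = doc["geometry"]
    layers = {}
    for lname, bounds in geo["layers"].items():
        _require(lname in LAYERS, f"geometry.layers.{lname}: unknown layer")
        lo, hi = float(bounds[0]), float(bounds[1])
        _require(hi > lo, f"geometry.layers.{lname}: empty bounds")
        layers[lname] = (lo, hi)
    geometry = LayerGeometry(
        longitudinal_um=float(geo["longitudinal_um"]),
        transverse_um=float(geo["transverse_um"]),
        layers=layers,
    )
    _require(geometry.longitudinal_um > 0 and geometry.transverse_um > 0,
             "geometry: extents must be positive")
    ordered = sorted(layers.values())
    for (lo1, hi1), (lo2, hi2) in zip(ordered, ordered[1:]):
        _require(hi1 <= lo2,
                 f"geometry.layers: overlapping bounds ({lo1},{hi1}) and ({lo2},{hi2})")

    afferents = {}
    for name, a in (doc.get("afferents") or {}).items():
        count = int(a["count"])
        _require(count >= 0, f"afferents.{name}.count: negative count")
        afferents[name] = AfferentSpec(
            name=name, count=count, rate_hz=float(a.get("rate_hz", 0.0)),
            layer=a.get("layer", "SR"),
        )

    channels = {}
    for name, c in (doc.get("synapse_channels") or {}).items():
        ch = SynapseChannel(name, float(c["tau1_ms"]), float(c["tau2_ms"]),
                            float(c["e_rev_mv"]))
        _require(0 < ch.tau1_ms < ch.tau2_ms,
                 f"synapse_channels.{name}: require 0 < tau1 < tau2")
        channels[name] = ch

    profiles = {}
    for name, p in (doc.get("axonal_profiles") or {}).items():
        prof = AxonalProfile(float(p["mean_um"]), float(p["sd_um"]),
                             float(p["extent_um"]), float(p.get("bin_um", 100.0)))
        _require(prof.sd_um > 0 and prof.extent_um > 0 and prof.bin_um > 0,
                 f"axonal_profiles.{name}: non-positive parameter")
        profiles[name] = prof

    valid_pre = set(cell_types) | set(afferents)
    projections: dict[tuple[str, str], Projection] = {}
    for pre, row in (doc.get("projections") or {}).items():
        _require(pre in valid_pre, f"projections.{pre}: unknown cell type in budget matrix")
        for post, e in (row or {}).items():
            _require(post in cell_types,
                     f"projections.{pre}.{post}: unknown cell type in budget matrix")
            syn = float(e["synapses"])
            _require(syn >= 0, f"projections.{pre}.{post}.synapses: negative count")
            spc = int(e.get("syn_per_conn", 1))
            _require(1 <= spc <= 10,
                     f"projections.{pre}.{post}.syn_per_conn: {spc} outside [1,10]")
            zones = tuple(e.get("zones", ("soma",)))
            for z in zones:
                _require(z in ZONES, f"projections.{pre}.{post}.zones: unknown zone {z!r}")
            projections[(pre, post)] = Projection(
                pre=pre, post=post, synapses=syn, syn_per_conn=spc,
                weight_ns=float(e.get("weight_ns", 0.0)),
                channel=e.get("channel", "AMPA"),
                zones=zones,
                gabab_weight_ns=float(e.get("gabab_weight_ns", 0.0)),
            )
            _require(projections[(pre, post)].channel in channels,
                     f"projections.{pre}.{post}.channel: unknown channel")

    neurons = {}
    for name, n in (doc.get("neurons") or {}).items():
        neurons[name] = NeuronParams(
            e_leak_mv=float(n["e_leak_mv"]), r_in_mohm=float(n["r_in_mohm"]),
            tau_m_ms=float(n["tau_m_ms"]), v_thresh_mv=float(n["v_thresh_mv"]),
            delta_t_mv=float(n.get("delta_t_mv", 2.0)),
            v_reset_mv=float(n.get("v_reset_mv", n["e_leak_mv"])),
            t_ref_ms=float(n.get("t_ref_ms", 2.0)),
            adapt_a_ns=float(n.get("adapt_a_ns", 0.0)),
            adapt_b_pa=float(n.get("adapt_b_pa", 0.0)),
            tau_w_ms=float(n.get("tau_w_ms", 100.0)),
        )
        _require(neurons[name].r_in_mohm > 0 and neurons[name].tau_m_ms > 0,
                 f"neurons.{name}: R and tau_m must be positive")

    for name, t in cell_types.items():
        _require(t.neuron_params_ref in neurons,
                 f"cell_types.{name}.neuron: unknown neuron parameter set")
        if t.count > 0:
            lo, hi = geometry.layers.get(t.layer, (0.0, 0.0))
            _require(hi > lo, f"cell_types.{name}: layer {t.layer} has zero volume")

    cfg = NetworkConfig(
        name=doc.get("name", "unnamed"),
        seed=int(doc.get("seed", 0)),
        cell_types=cell_types,
        geometry=geometry,
        budgets=SynapseBudgetMatrix(projections),
        profiles=profiles,
        afferents=afferents,
        channels=channels,
        neurons=neurons,
        ephys_targets=doc.get("ephys_targets", {}) or {},
        sweep_protocols=doc.get("sweep_protocols", {}) or {},
        scale_fraction=float(doc.get("scale_fraction", 1.0)),
        scale_mode=doc.get("scale_mode"),
        conduction_velocity_um_per_ms=float(doc.get("conduction_velocity_um_per_ms", 300.0)),
        delay_offset_ms=float(doc.get("delay_offset_ms", 0.5)),
    )
    principals = cfg.principal_types
    _require(len(principals) >= 1, "cell_types: no principal type declared")
    return cfg


def config_to_dict(cfg: NetworkConfig) -> dict:
    """Inverse of :func:`config_from_dict` (used for digests and round-trips)."""
    doc = {
        "name": cfg.name,
        "seed": cfg.seed,
        "scale_fraction": cfg.scale_fraction,
        "scale_mode": cfg.scale_mode,
        "conduction_velocity_um_per_ms": cfg.conduction_velocity_um_per_ms,
        "delay_offset_ms": cfg.delay_offset_ms,
        "geometry": {
            "longitudinal_um": cfg.geometry.longitudinal_um,
            "transverse_um": cfg.geometry.transverse_um,
            "layers": {k: list(v) for k, v in cfg.geometry.layers.items()},
        },
        "cell_types": {
            n: {"count": t.count, "layer": t.layer, "is_principal": t.is_principal,
                "neuron": t.neuron_params_ref}
            for n, t in cfg.cell_types.items()
        },
        "afferents": {
            n: {"count": a.count, "rate_hz": a.rate_hz, "layer": a.layer}
            for n, a in cfg.afferents.items()
        },
        "synapse_channels": {
            n: {"tau1_ms": c.tau1_ms, "tau2_ms": c.tau2_ms, "e_rev_mv": c.e_rev_mv}
            for n, c in cfg.channels.items()
        },
        "axonal_profiles": {
            n: {"mean_um": p.mean_um, "sd_um": p.sd_um, "extent_um": p.extent_um,
                "bin_um": p.bin_um}
            for n, p in cfg.profiles.items()
        },
        "neurons": {
            n: {"e_leak_mv": p.e_leak_mv, "r_in_mohm": p.r_in_mohm,
                "tau_m_ms": p.tau_m_ms, "v_thresh_mv": p.v_thresh_mv,
                "delta_t_mv": p.delta_t_mv, "v_reset_mv": p.v_reset_mv,
                "t_ref_ms": p.t_ref_ms, "adapt_a_ns": p.adapt_a_ns,
                "adapt_b_pa": p.adapt_b_pa, "tau_w_ms": p.tau_w_ms}
            for n, p in cfg.neurons.items()
        },
        "projections": {},
        "ephys_targets": copy.deepcopy(cfg.ephys_targets),
        "sweep_protocols": copy.deepcopy(cfg.sweep_protocols),
    }
    for (pre, post), p in cfg.budgets.items():
        row = doc["projections"].setdefault(pre, {})
        row[post] = {"synapses": p.synapses, "syn_per_conn": p.syn_per_conn,
                     "weight_ns": p.weight_ns, "channel": p.channel,
                     "zones": list(p.zones)}
        if p.gabab_weight_ns:
            row[post]["gabab_weight_ns"] = p.gabab_weight_ns
    return doc


def load_config(config_text: str) -> NetworkConfig:
    """Parse and validate a YAML configuration document."""
    doc = yaml.safe_load(config_text)
    return config_from_dict(doc)


def load_config_file(path) -> NetworkConfig:
    with open(path) as fh:
        return load_config(fh.read())


def default_config() -> NetworkConfig:
    """The packaged full-scale CA1 configuration."""
    text = resources.files("ca1net.data").joinpath("full_scale.yaml").read_text()
    return load_config(text)


def save_config(cfg: NetworkConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Census and rescaling
# ---------------------------------------------------------------------------

def census(config: NetworkConfig) -> CensusReport:
    """Totals of all cells, principal cells, interneurons and afferent units."""
    per_type = {n: t.count for n, t in config.cell_types.items()}
    principal = sum(t.count for t in config.cell_types.values() if t.is_principal)
    total = sum(per_type.values())
    return CensusReport(
        total=total,
        principal=principal,
        interneurons=total - principal,
        afferent_units=sum(a.count for a in config.afferents.values()),
        per_type=per_type,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _scaled_counts(counts: dict[str, int], fraction: float) -> dict[str, int]:
    """Round half up per type (>=1 where originally >0), then fix the total
    by adjusting the largest type so proportions are preserved."""
    scaled = {}
    for name, n in counts.items():
        if n == 0:
            scaled[name] = 0
        else:
            scaled[name] = max(1, _round_half_up(n * fraction))
    target_total = max(len([n for n in counts.values() if n > 0]),
                       _round_half_up(sum(counts.values()) * fraction))
    if scaled:
        largest = max(counts, key=lambda k: counts[k])
        scaled[largest] += target_total - sum(scaled.values())
        scaled[largest] = max(scaled[largest], 1 if counts[largest] > 0 else 0)
    return scaled


def scale_config(config: NetworkConfig, fraction: float,
                 mode: str = "preserve_probability") -> NetworkConfig:
    """Rescale the network to ``fraction`` of its size.

    ``preserve_convergence`` keeps per-cell in-degrees (budgets scale by the
    fraction, weights unchanged); ``preserve_probability`` keeps pairwise
    connection probability (budgets scale by fraction squared) and multiplies
    per-connection weights by 1/fraction so the expected total synaptic drive
    per cell is conserved.
    """
    if not (0.0 < fraction <= 1.0):
        raise ConfigError(f"fraction {fraction} outside (0, 1]")
    if mode not in SCALING_MODES:
        raise ConfigError(f"unknown scaling mode {mode!r}")
    if fraction == 1.0:
        return copy.deepcopy(config)

    cfg = copy.deepcopy(config)
    cell_counts = _scaled_counts({n: t.count for n, t in cfg.cell_types.items()},
                                 fraction)
    cfg.cell_types = {
        n: replace(t, count=cell_counts[n]) for n, t in cfg.cell_types.items()
    }
    aff_counts = _scaled_counts({n: a.count for n, a in cfg.afferents.items()},
                                fraction)
    cfg.afferents = {
        n: replace(a, count=aff_counts[n]) for n, a in cfg.afferents.items()
    }

    if mode == "preserve_convergence":
        budget_factor, weight_factor = fraction, 1.0
    else:
        budget_factor, weight_factor = fraction * fraction, 1.0 / fraction

    def rescale(p: Projection) -> Projection:
        return replace(
            p,
            synapses=p.synapses * budget_factor,
            weight_ns=p.weight_ns * weight_factor,
            gabab_weight_ns=p.gabab_weight_ns * weight_factor,
        )

    cfg.budgets = cfg.budgets.map(rescale)
    cfg.scale_fraction = config.scale_fraction * fraction
    cfg.scale_mode = mode
    return cfg
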