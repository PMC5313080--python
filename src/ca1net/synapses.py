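"""Double-exponential conductance synapses, paired recordings, charge matching.

The conductance waveform is g(t) = g_max * N * (exp(-t/tau2) - exp(-t/tau1))
with N chosen so the peak equals g_max.  Mixed GABA-A,B synapses (the
neurogliaform output) superpose a fast GABA-A and a slow GABA-B component
with distinct reversal potentials (-60 / -90 mV packaged defaults).  Charge
transfer has the closed form integral g_max * N * (tau2 - tau1) * dV, which
is what the charge-matching perturbation equates when it replaces the slow
GABA-B component with a scaled-up fast GABA-A conductance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig, Projection, SynapseChannel

ZONE_ATTENUATION = {
    # stand-in for dendritic filtering between synapse zone and the soma
    "AIS": 1.0,
    "soma": 1.0,
    "proximal_dendrite_SO": 0.9,
    "proximal_dendrite_SR": 0.9,
    "basal_dendrite": 0.85,
    "distal_dendrite_SLM": 0.7,
}


@dataclass(frozen=True)
class SynapseParams:
    tau1_ms: float
    tau2_ms: float
    g_max_ns: float
    e_rev_mv: float

    def __post_init__(self):
        if not (0 < self.tau1_ms < self.tau2_ms):
            raise ValueError(f"require 0 < tau1 < tau2, got "
                             f"({self.tau1_ms}, {self.tau2_ms})")
        if self.g_max_ns < 0:
            raise ValueError("g_max must be non-negative")

    @classmethod
    def from_channel(cls, ch: SynapseChannel, g_max_ns: float) -> "SynapseParams":
        return cls(ch.tau1_ms, ch.tau2_ms, g_max_ns, ch.e_rev_mv)


@dataclass
class PSCMeasurement:
    peak_pa: float
    rise_10_90_ms: float
    decay_tau_ms: float
    trials: int
    t_ms: np.ndarray | None = None
    i_pa: np.ndarray | None = None   # trial-averaged current trace


def peak_time(tau1_ms: float, tau2_ms: float) -> float:
    """Time of the conductance maximum."""
    return (tau1_ms * tau2_ms / (tau2_ms - tau1_ms)) * math.log(tau2_ms / tau1_ms)


def norm_factor(tau1_ms: float, tau2_ms: float) -> float:
    """N such that max of N*(exp(-t/tau2) - exp(-t/tau1)) is 1."""
    tp = peak_time(tau1_ms, tau2_ms)
    return 1.0 / (math.exp(-tp / tau2_ms) - math.exp(-tp / tau1_ms))


def conductance_waveform(syn: SynapseParams, t_ms) -> np.ndarray:
    """g(t) in nS for one activation at t = 0; zero for t < 0."""
    t = np.asarray(t_ms, dtype=float)
    n = norm_factor(syn.tau1_ms, syn.tau2_ms)
    g = syn.g_max_ns * n * (np.exp(-t / syn.tau2_ms) - np.exp(-t / syn.tau1_ms))
    return np.where(t >= 0, g, 0.0)


def synaptic_charge(syn: SynapseParams, driving_force_mv: float,
                    horizon_ms: float | None = None) -> float:
    """Charge transfer integral g(t)*dV dt in pC (nS*mV*ms = fC; /1000 -> pC).

    With no horizon, uses the closed form g_max*N*(tau2 - tau1)*dV; a finite
    horizon integrates numerically (the horizon should be >> tau2).
    """
    n = norm_factor(syn.tau1_ms, syn.tau2_ms)
    if horizon_ms is None:
        q = syn.g_max_ns * n * (syn.tau2_ms - syn.tau1_ms) * driving_force_mv
        return q / 1000.0
    t = np.linspace(0.0, horizon_ms, max(2, int(horizon_ms / 0.05)))
    g = conductance_waveform(syn, t)
    return float(np.trapezoid(g * driving_force_mv, t)) / 1000.0


def charge_match_scale(gabaa: SynapseParams, gabab: SynapseParams,
                       reference_mv: float = -50.0) -> float:
    """Factor k such that k * charge(GABA-A) = charge(GABA-B).

    Charges are evaluated at a common reference potential so each component
    sees its own driving force (reference - reversal).
    """
    qa = synaptic_charge(gabaa, reference_mv - gabaa.e_rev_mv)
    qb = synaptic_charge(gabab, reference_mv - gabab.e_rev_mv)
    if qa == 0.0:
        raise ZeroDivisionError("GABA-A component carries zero charge")
    return qb / qa


def projection_components(cfg: NetworkConfig, proj: Projection) -> list[SynapseParams]:
    """The synaptic component(s) of one projection (two for mixed GABA-A,B)."""
    comps = [SynapseParams.from_channel(cfg.channels[proj.channel], proj.weight_ns)]
    if proj.is_mixed:
        comps.append(SynapseParams.from_channel(cfg.channels["GABAB"],
                                                proj.gabab_weight_ns))
    return comps


def paired_recording(cfg: NetworkConfig, pre_type: str, post_type: str,
                     hold_mv: float = -50.0, trials: int = 10,
                     rng: np.random.Generator | None = None,
                     duration_ms: float = 1000.0,
                     dt_ms: float = 0.1) -> PSCMeasurement:
    """Simulated paired recording under ideal voltage clamp.

    A presynaptic spike is triggered at t = 0 and the postsynaptic current
    I(t) = sum_components n_syn * g(t) * (V_hold - E_rev) is measured at the
    soma.  Trial-to-trial variability enters only through the randomly chosen
    connection location: each trial resamples the synapse zone, which scales
    the effective conductance by the zone's attenuation factor.
    """
    if (pre_type, post_type) not in cfg.budgets:
        raise KeyError(f"undeclared pair ({pre_type}, {post_type})")
    proj = cfg.budgets[(pre_type, post_type)]
    rng = rng or np.random.default_rng(0)
    comps = projection_components(cfg, proj)

    t = np.arange(0.0, duration_ms, dt_ms)
    traces = np.zeros((trials, t.size))
    for k in range(trials):
        zone = proj.zones[rng.integers(len(proj.zones))]
        att = ZONE_ATTENUATION[zone]
        for syn in comps:
            g = conductance_waveform(syn, t) * proj.syn_per_conn * att
            traces[k] += g * (hold_mv - syn.e_rev_mv)
    mean = traces.mean(axis=0)

    if np.allclose(mean, 0.0):
        return PSCMeasurement(0.0, float("nan"), float("nan"), trials, t, mean)
    k_peak = int(np.argmax(np.abs(mean)))
    peak = float(mean[k_peak])
    # 10-90% rise time on the rising limb toward the (absolute) peak
    a = np.abs(mean[: k_peak + 1])
    t10 = t[np.searchsorted(a, 0.1 * abs(peak))]
    t90 = t[np.searchsorted(a, 0.9 * abs(peak))]
    # decay time constant by log-linear fit over the 90%..10% falling limb
    tail = np.abs(mean[k_peak:])
    lo = 0.1 * abs(peak)
    end = np.nonzero(tail <= lo)[0]
    end = end[0] if end.size else tail.size
    seg = tail[:end]
    if seg.size > 3:
        slope = np.polyfit(t[k_peak:k_peak + seg.size], np.log(seg), 1)[0]
        decay = -1.0 / slope if slope < 0 else float("nan")
    else:
        decay = float("nan")
    return PSCMeasurement(peak, float(t90 - t10), float(decay), trials, t, mean)
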