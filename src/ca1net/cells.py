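"""Reduced single-compartment neuron models and characterization protocols.

Each cell type is an adaptive exponential integrate-and-fire (AdEx) neuron
whose passive core (resting potential, input resistance, membrane time
constant) is pinned directly to the measured electrophysiology, with the
exponential take-off potential placed so the steady-state rheobase
g_L (V_T - Delta_T - E_L) matches the reported rheobase.  The
characterization protocol mirrors standard current-clamp practice: resting
potential from a zero-current epoch, input resistance and time constant from
the smallest hyperpolarizing step, rheobase by bisection on 500 ms steps to
1 pA, and spike threshold at the point where dV/dt crosses 20 mV/ms.

Units throughout: mV, ms, pA, MOhm, nS, pF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import NeuronParams

DT_MIN, DT_MAX = 0.01, 0.025
_EXP_CLIP = 16.0  # cap on (V - V_T)/Delta_T inside the spike-initiation term


@dataclass
class VmTrace:
    t_ms: np.ndarray
    vm_mv: np.ndarray
    spike_times_ms: np.ndarray
    dt_ms: float


@dataclass
class EphysProfile:
    rmp_mv: float
    rin_mohm: float
    tau_m_ms: float
    rheobase_pa: float          # nan when no spike at the maximum current
    threshold_mv: float
    delay_first_spike_ms: float
    half_width_ms: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def membrane_step(params: NeuronParams, i_inj_pa, duration_ms: float,
                  dt_ms: float = 0.025, v0_mv: float | None = None) -> VmTrace:
    """Integrate one AdEx neuron under a current injection.

    ``i_inj_pa`` may be a scalar (step current) or an array with one value per
    time step.  Subthreshold, with zero adaptation, the response of the
    passive core relaxes exponentially toward E_L + I*R.
    """
    if dt_ms <= 0:
        raise ValueError(f"non-positive dt {dt_ms}")
    n = int(round(duration_ms / dt_ms))
    i_inj = np.broadcast_to(np.asarray(i_inj_pa, dtype=float), (n,))

    e_l, g_l, c = params.e_leak_mv, params.g_leak_ns, params.c_pf
    v_t, d_t = params.v_thresh_mv, params.delta_t_mv
    v_spike = params.v_spike_mv
    ref_steps = int(round(params.t_ref_ms / dt_ms))

    v = e_l if v0_mv is None else float(v0_mv)
    w = 0.0
    vm = np.empty(n)
    spikes = []
    ref = 0
    for k in range(n):
        if ref > 0:
            ref -= 1
            vm[k] = v
            w += dt_ms * (params.adapt_a_ns * (v - e_l) - w) / params.tau_w_ms
            continue
        i_exp = 0.0
        if d_t > 0:
            i_exp = g_l * d_t * math.exp(min((v - v_t) / d_t, _EXP_CLIP))
        dv = (-g_l * (v - e_l) + i_exp - w + i_inj[k]) / c
        v = v + dt_ms * dv
        w += dt_ms * (params.adapt_a_ns * (v - e_l) - w) / params.tau_w_ms
        crossed = v >= v_spike or (d_t == 0 and v >= v_t)
        if crossed:
            v = v_spike if d_t > 0 else v_t
            vm[k] = v
            spikes.append((k + 1) * dt_ms)
            v = params.v_reset_mv
            w += params.adapt_b_pa
            ref = ref_steps
        else:
            vm[k] = v
    t = np.arange(1, n + 1) * dt_ms
    return VmTrace(t, vm, np.asarray(spikes), dt_ms)


def _steady_vm(trace: VmTrace) -> float:
    tail = max(1, int(0.1 * len(trace.vm_mv)))
    return float(np.mean(trace.vm_mv[-tail:]))


def _fit_tau(trace: VmTrace, v_inf: float, v_start: float) -> float:
    """Single-exponential fit of the step onset by log-linear regression."""
    y = (trace.vm_mv - v_inf) / (v_start - v_inf)
    # use the initial decade of the relaxation, clear of noise-free asymptote
    mask = (y > 0.05) & (y < 0.95)
    if mask.sum() < 4:
        return float("nan")
    t, ly = trace.t_ms[mask], np.log(y[mask])
    slope = np.polyfit(t, ly, 1)[0]
    return float(-1.0 / slope) if slope < 0 else float("nan")


def measure_threshold(trace: VmTrace, dvdt_crit_mv_per_ms: float = 20.0) -> float:
    """Voltage at the first crossing of the dV/dt criterion before a spike."""
    if trace.spike_times_ms.size == 0:
        return float("nan")
    dvdt = np.diff(trace.vm_mv) / trace.dt_ms
    k_spike = int(round(trace.spike_times_ms[0] / trace.dt_ms)) - 1
    seg = dvdt[: max(k_spike, 1)]
    above = np.nonzero(seg >= dvdt_crit_mv_per_ms)[0]
    if above.size == 0:
        return float(trace.vm_mv[k_spike])
    return float(trace.vm_mv[above[0]])


def _half_width(trace: VmTrace, threshold_mv: float) -> float:
    """Width of the first spike excursion at half amplitude above threshold."""
    if trace.spike_times_ms.size == 0 or not np.isfinite(threshold_mv):
        return float("nan")
    peak = float(np.max(trace.vm_mv))
    half = threshold_mv + 0.5 * (peak - threshold_mv)
    above = trace.vm_mv >= half
    if not above.any():
        return float("nan")
    runs = np.diff(above.astype(int))
    starts = np.nonzero(runs == 1)[0]
    ends = np.nonzero(runs == -1)[0]
    if starts.size == 0 or ends.size == 0:
        return trace.dt_ms
    return float(max(trace.dt_ms, (ends[0] - starts[0]) * trace.dt_ms))


def rheobase_search(params: NeuronParams, i_max_pa: float,
                    step_ms: float = 500.0, dt_ms: float = 0.025,
                    tol_pa: float = 1.0) -> float:
    """Smallest 500 ms step current that elicits a spike, by bisection."""
    def spikes_at(i_pa: float) -> bool:
        return membrane_step(params, i_pa, step_ms, dt_ms).spike_times_ms.size > 0

    if not spikes_at(i_max_pa):
        return float("nan")
    lo, hi = 0.0, float(i_max_pa)
    while hi - lo > tol_pa:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


def sweep_currents(protocol: dict[str, float]) -> np.ndarray:
    """Current grid of a characterization sweep (hyperpolarized..depolarized)."""
    return np.arange(protocol["hyper_pa"],
                     protocol["depol_pa"] + 0.5 * protocol["step_pa"],
                     protocol["step_pa"])


def characterize(params: NeuronParams, sweep: np.ndarray,
                 step_ms: float = 500.0, dt_ms: float = 0.025) -> EphysProfile:
    """Run the current-sweep protocol and extract the standard profile."""
    sweep = np.asarray(sweep, dtype=float)
    if not (sweep.min() < 0 < sweep.max()):
        raise ValueError("sweep must span sub- and supra-threshold currents")

    rest = membrane_step(params, 0.0, step_ms, dt_ms)
    rmp = _steady_vm(rest)

    i_hyp = float(sweep[sweep < 0].max())  # smallest hyperpolarizing step
    hyp = membrane_step(params, i_hyp, step_ms, dt_ms, v0_mv=rmp)
    v_inf = _steady_vm(hyp)
    rin = (v_inf - rmp) / i_hyp * 1000.0   # mV/pA -> MOhm
    tau = _fit_tau(hyp, v_inf, rmp)

    rheo = rheobase_search(params, float(sweep.max()), step_ms, dt_ms)
    if math.isnan(rheo):
        return EphysProfile(rmp, rin, tau, float("nan"), float("nan"),
                            float("nan"), float("nan"))
    # threshold and spike shape read at the rheobase trace itself
    tr = membrane_step(params, rheo, step_ms, min(dt_ms, 0.01))
    if tr.spike_times_ms.size == 0:  # guard: bisection tolerance edge
        tr = membrane_step(params, rheo + 1.0, step_ms, min(dt_ms, 0.01))
    thr = measure_threshold(tr)
    delay = float(tr.spike_times_ms[0]) if tr.spike_times_ms.size else float("nan")
    return EphysProfile(rmp, rin, tau, rheo, thr, delay, _half_width(tr, thr))


def fi_curve(params: NeuronParams, currents_pa, duration_ms: float = 1000.0,
             dt_ms: float = 0.025) -> np.ndarray:
    """Firing rate (Hz) for each injected current."""
    rates = []
    for i_pa in np.atleast_1d(currents_pa):
        tr = membrane_step(params, float(i_pa), duration_ms, dt_ms)
        rates.append(tr.spike_times_ms.size / (duration_ms / 1000.0))
    return np.asarray(rates)
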