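"""End-to-end experiment driver: the perturbation battery at configurable scale.

Each named condition (control, tonic-excitation sweep, per-type output muting,
pyramidal-recurrence scaling, 50% class muting, interneuron homogenization
stages, GABA-B removal and charge-matched compensation) is expressed as a
configuration transform plus optional weight-level perturbation, then built,
simulated and analyzed identically.  The analysis emits one row per run in
the shape of the spectral summary table: peak frequency and power within the
theta and gamma bands and overall, from the Welch periodogram of the
pyramidal-cell spike density function.

At reduced scale the spike density function is computed over all pyramidal
cells (the full-scale electrode-local subset would hold too few cells to be
informative); firing-rate and phase reports follow the same convention.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import analysis
from .builder import build_circuit
from .config import NetworkConfig, default_config, scale_config
from .engine import Network, SimResult, simulate
from .perturb import (PV_CLASS, SOM_CLASS, charge_matched_gabaa,
                      homogenize_interneurons, mute_outputs, remove_gabab,
                      scale_pyr_pyr)

EXCITATION_SWEEP_HZ = (0.2, 0.4, 0.5, 0.65, 0.8, 1.0, 1.2, 1.4)
PYR2PYR_FACTORS = (0.0, 0.5, 2.0)


@dataclass
class ConditionResult:
    name: str
    seed: int
    result: SimResult
    sdf_rate: np.ndarray
    summary: dict[str, float]


def battery_entries(cfg: NetworkConfig | None = None) -> list[str]:
    cfg = cfg or default_config()
    entries = ["control"]
    entries += [f"excitation:{r:g}" for r in EXCITATION_SWEEP_HZ]
    entries += [f"mute:{t}" for t in cfg.cell_types]
    entries += [f"pyr2pyr:{f:g}" for f in PYR2PYR_FACTORS]
    entries += ["mute_pv_50", "mute_som_50"]
    entries += [f"homogenize:{s}" for s in
                ("ephys", "input_weights", "input_numbers", "full")]
    entries += ["gabab_removed", "gabab_charge_matched"]
    return entries


def _with_rate(cfg: NetworkConfig, rate_hz: float) -> NetworkConfig:
    out = copy.deepcopy(cfg)
    out.afferents = {n: replace(a, rate_hz=rate_hz)
                     for n, a in out.afferents.items()}
    return out


def prepare_condition(cfg: NetworkConfig, entry: str
                      ) -> tuple[NetworkConfig, list]:
    """Resolve a battery entry into (configuration, weight-level ops)."""
    ops = []
    if entry == "control":
        return cfg, ops
    if entry.startswith("excitation:"):
        return _with_rate(cfg, float(entry.split(":")[1])), ops
    if entry.startswith("mute:"):
        t = entry.split(":")[1]
        if t not in cfg.cell_types:
            raise KeyError(f"unknown battery entry {entry!r}")
        ops.append(lambda net, seed: mute_outputs(net, t, 1.0, seed))
        return cfg, ops
    if entry.startswith("pyr2pyr:"):
        return scale_pyr_pyr(cfg, float(entry.split(":")[1])), ops
    if entry == "mute_pv_50":
        ops += [(lambda t_: lambda net, seed: mute_outputs(net, t_, 0.5, seed))(t)
                for t in PV_CLASS]
        return cfg, ops
    if entry == "mute_som_50":
        ops += [(lambda t_: lambda net, seed: mute_outputs(net, t_, 0.5, seed))(t)
                for t in SOM_CLASS]
        return cfg, ops
    if entry.startswith("homogenize:"):
        return homogenize_interneurons(cfg, entry.split(":")[1]), ops
    if entry == "gabab_removed":
        ops.append(lambda net, seed: remove_gabab(net))
        return cfg, ops
    if entry == "gabab_charge_matched":
        ops.append(lambda net, seed: charge_matched_gabaa(net))
        return cfg, ops
    raise KeyError(f"unknown battery entry {entry!r}")


def spectral_row(result: SimResult, population: str = "Pyr",
                 crop_ms: float = 50.0, bin_ms: float = 1.0,
                 segment_ms: float | None = None,
                 positions=None, centre_um: float | None = None,
                 local_halfwidth_um: float = 500.0) -> tuple[dict, np.ndarray]:
    """Theta/gamma/overall peak frequency and power of a population SDF.

    With ``positions`` supplied the SDF is computed from the cells inside a
    longitudinal window around ``centre_um`` (default: prism midline),
    mirroring the electrode-local spike selection of the full-scale analysis;
    theta is locally coherent but drifts in phase along the septotemporal
    axis, so a whole-prism SDF would wash the oscillation out.
    """
    gids, t = result.raster_of(population)
    if positions is not None:
        x = positions.xyz[:, 0]
        if centre_um is None:
            centre_um = 0.5 * (x.min() + x.max())
        keep = np.abs(x[gids] - centre_um) < local_halfwidth_um
        t = t[keep]
    t = t[t >= crop_ms]
    _, rate = analysis.sdf(t - crop_ms, result.duration_ms - crop_ms,
                           bin_ms=bin_ms)
    fs = 1000.0 / bin_ms
    seg = segment_ms or min(1024.0, result.duration_ms - crop_ms)
    if rate.size < int(seg * fs / 1000.0):
        seg = rate.size / fs * 1000.0
    psd = analysis.welch_psd(rate, fs, segment_ms=seg)
    th_f, th_p = psd.band_peak(*analysis.THETA_BAND)
    ga_f, ga_p = psd.band_peak(*analysis.GAMMA_BAND)
    row = {"theta_freq_hz": th_f, "theta_power": th_p,
           "gamma_freq_hz": ga_f, "gamma_power": ga_p,
           "peak_freq_hz": psd.peak_hz, "peak_power": psd.peak_power,
           "n_spikes": int(t.size)}
    return row, rate


def run_condition(entry: str, scale: float = 0.015, seed: int = 1,
                  duration_ms: float = 2000.0, dt_ms: float = 0.025,
                  base_cfg: NetworkConfig | None = None,
                  mode: str = "preserve_probability") -> ConditionResult:
    """Build, simulate and analyze one battery condition at reduced scale."""
    cfg = base_cfg or default_config()
    if scale < 1.0:
        cfg = scale_config(cfg, scale, mode)
    cfg, ops = prepare_condition(cfg, entry)
    positions, edges = build_circuit(cfg, seed)
    net = Network(cfg, positions, edges)
    for op in ops:
        op(net, seed)
    result = simulate(net, duration_ms=duration_ms, dt_ms=dt_ms, seed=seed)
    row, rate = spectral_row(result, positions=positions)
    row["entry"] = entry
    row["seed"] = seed
    return ConditionResult(entry, seed, result, rate, row)


def run_battery(entries: list[str], scale: float = 0.015, seeds=(1,),
                duration_ms: float = 2000.0,
                base_cfg: NetworkConfig | None = None) -> pd.DataFrame:
    rows = []
    for entry in entries:
        for seed in seeds:
            rows.append(run_condition(entry, scale, seed, duration_ms,
                                      base_cfg=base_cfg).summary)
    return pd.DataFrame(rows)


def theta_muting_runs(seeds=(1, 2, 3), scale: float = 0.015,
                      duration_ms: float = 4000.0) -> list[dict[str, float]]:
    """Control vs pyramidal-output-muted runs of the reduced-scale network.

    For each seed, runs the 0.65 Hz-driven control and the same circuit with
    every pyramidal cell's output muted, and reports the electrode-local
    pyramidal SDF theta peak (frequency, power), the overall peak frequency,
    and the pooled-interneuron theta power for both conditions.
    """
    out = []
    for seed in seeds:
        ctrl = run_condition("control", scale, seed, duration_ms)
        mute = run_condition("mute:Pyr", scale, seed, duration_ms)
        row = {"seed": seed,
               "control_peak_freq_hz": ctrl.summary["peak_freq_hz"],
               "control_theta_freq_hz": ctrl.summary["theta_freq_hz"],
               "control_theta_power": ctrl.summary["theta_power"],
               "muted_theta_power": mute.summary["theta_power"]}
        for label, cond in (("control", ctrl), ("muted", mute)):
            ts = np.concatenate(
                [cond.result.raster_of(p)[1]
                 for p in ("PVB", "CCKB", "SCA", "Axo", "Bis", "OLM", "NGF",
                           "Ivy")])
            ts = ts[ts >= 50.0]
            _, rate = analysis.sdf(ts - 50.0, duration_ms - 50.0)
            psd = analysis.welch_psd(rate, 1000.0, segment_ms=1024.0)
            row[f"{label}_interneuron_theta_power"] = \
                psd.band_peak(*analysis.THETA_BAND)[1]
        out.append(row)
    return out


def gabab_anova(scale: float = 0.015, seeds=(1, 2, 3),
                duration_ms: float = 2000.0,
                base_cfg: NetworkConfig | None = None
                ) -> tuple[pd.DataFrame, float, float]:
    """Three replicates of control / GABA-B removed / charge-matched, with a
    one-way ANOVA on theta-band peak power across the conditions."""
    entries = ("control", "gabab_removed", "gabab_charge_matched")
    table = run_battery(list(entries), scale, seeds, duration_ms, base_cfg)
    groups = [table.loc[table["entry"] == e, "theta_power"].to_numpy()
              for e in entries]
    f_stat, p = stats.f_oneway(*groups)
    return table, float(f_stat), float(p)
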