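"""Regenerate the packaged full-scale configuration
(src/ca1net/data/full_scale.yaml).

The cell census, synapse-budget matrix and electrophysiological targets are
data; geometry, axonal Gaussians, synaptic kinetics and conductances are
documented estimates (see docs/methods.md for provenance and calibration).

Run from the repository root:  python scripts/make_config.py
"""
import sys
from pathlib import Path

import yaml

# synapse-budget matrix: total synapses per (presynaptic row, postsynaptic
# column) pair, including the afferent CA3/ECIII rows
COLS = ["Axo", "Bis", "CCKB", "Ivy", "NGF", "OLM", "Pyr", "PVB", "SCA"]
BUDGET = {
    "Axo":  [0, 0, 0, 0, 0, 0, 1.12e7, 0, 0],
    "Bis":  [2.35e5, 3.54e5, 5.76e5, 2.64e5, 0, 6.40e5, 3.12e7, 8.85e5, 6.80e4],
    "CCKB": [1.41e5, 2.12e5, 9.79e5, 5.64e5, 0, 2.62e5, 3.24e7, 5.31e5, 8.32e4],
    "Ivy":  [3.53e5, 5.30e5, 3.42e6, 2.11e6, 1.00e6, 2.23e6, 1.28e8, 1.33e6, 4.08e5],
    "NGF":  [0, 0, 0, 0, 6.09e5, 0, 4.36e7, 0, 0],
    "OLM":  [1.18e5, 1.77e5, 1.44e6, 0, 4.65e5, 9.84e4, 2.49e7, 4.42e5, 1.60e5],
    "Pyr":  [7.19e5, 2.43e6, 0, 2.38e5, 0, 1.17e7, 6.14e7, 7.03e6, 1.26e5],
    "PVB":  [5.73e4, 8.62e4, 1.37e5, 7.05e4, 0, 0, 5.83e7, 2.16e5, 9.60e3],
    "SCA":  [8.82e3, 1.33e4, 1.30e5, 1.06e5, 0, 1.97e4, 3.74e6, 3.32e4, 1.44e4],
    "CA3":  [1.23e7, 2.56e7, 1.44e7, 3.39e7, 0, 0, 3.73e9, 6.69e7, 1.55e6],
    "ECIII": [1.43e6, 1.91e6, 4.02e6, 0, 3.75e6, 0, 8.09e8, 0, 4.58e5],
}

COUNTS = {"Pyr": 311500, "PVB": 5530, "CCKB": 3600, "SCA": 400, "Axo": 1470,
          "Bis": 2210, "OLM": 1640, "NGF": 3580, "Ivy": 8810}
LAYER = {"Pyr": "SP", "PVB": "SP", "CCKB": "SP", "SCA": "SR", "Axo": "SP",
         "Bis": "SP", "OLM": "SO", "NGF": "SLM", "Ivy": "SP"}

# electrophysiological targets per type:
# RMP (mV), Rin (MOhm), tau_m (ms), rheobase (pA), threshold (mV),
# delay to first spike (ms), spike half-width (ms)
EPHYS = {
    "Pyr":  (-63.0, 62.2, 4.8, 250.0, 52.0, 12.4, 80.7),
    "PVB":  (-65.0, 52.0, 6.9, 300.0, -36.6, 74.6, 0.9),
    "CCKB": (-70.6, 211.0, 22.6, 60.0, -40.6, 166.6, 1.9),
    "SCA":  (-70.5, 272.4, 24.4, 40.0, -43.1, 127.7, 1.6),
    "Axo":  (-65.0, 52.0, 7.0, 200.0, -41.6, 43.5, 0.6),
    "Bis":  (-67.0, 98.7, 14.7, 350.0, -28.1, 28.4, 0.5),
    "OLM":  (-71.5, 343.8, 22.4, 50.0, 100.2, 8.9, 112.9),
    "Ivy":  (-60.0, 100.0, 21.1, 160.0, -27.6, 173.3, 0.6),
    "NGF":  (-60.0, 100.0, 21.1, 170.0, -27.7, 119.0, 0.6),
}
# threshold/half-width entries that are physiologically implausible misprints
ANOMALOUS_THRESHOLD = {"Pyr", "OLM"}

# current-sweep protocols (hyperpolarized start, step, depolarized end, pA);
# types without a published grid get one spanning their rheobase
SWEEPS = {
    "PVB":  (-300.0, 50.0, 500.0),
    "CCKB": (-100.0, 20.0, 80.0),
    "OLM":  (-130.0, 30.0, 80.0),
    "NGF":  (-130.0, 20.0, 190.0),
    "Pyr":  (-200.0, 50.0, 400.0),
    "SCA":  (-100.0, 20.0, 80.0),
    "Axo":  (-200.0, 50.0, 350.0),
    "Bis":  (-200.0, 50.0, 500.0),
    "Ivy":  (-130.0, 30.0, 250.0),
}

# adaptation: fast-spiking types adapt weakly; pyramidal adaptation
# (b, tau_w) sets the post-burst recovery that paces the population rhythm
ADAPT = {  # (a_nS, b_pA, tau_w_ms, t_ref_ms)
    "Pyr":  (0.0, 80.0, 130.0, 2.0),
    "PVB":  (0.0, 2.0, 30.0, 1.0),
    "Axo":  (0.0, 2.0, 30.0, 1.0),
    "Bis":  (0.0, 5.0, 50.0, 1.0),
    "CCKB": (0.0, 15.0, 100.0, 2.0),
    "SCA":  (0.0, 15.0, 100.0, 2.0),
    "OLM":  (0.0, 25.0, 150.0, 2.0),
    "Ivy":  (0.0, 15.0, 120.0, 2.0),
    "NGF":  (0.0, 15.0, 120.0, 2.0),
}
# spike sharpness fitted by scripts/fit_cells.py (grid search on the
# measured dV/dt threshold); anomalous-threshold cells keep the default 2.0
DELTA_T = {"Pyr": 2.0, "PVB": 2.5, "CCKB": 3.0, "SCA": 2.5, "Axo": 2.5,
           "Bis": 0.5, "OLM": 2.0, "Ivy": 2.5, "NGF": 2.5}

# axonal bouton-distance Gaussians (documented estimates; source data are
# figure-only): mean, SD, maximum extent (um)
PROFILES = {
    "Pyr":  (300.0, 300.0, 2000.0),
    "PVB":  (200.0, 200.0, 1000.0),
    "CCKB": (200.0, 200.0, 900.0),
    "SCA":  (200.0, 200.0, 800.0),
    "Axo":  (150.0, 150.0, 600.0),
    "Bis":  (250.0, 250.0, 1000.0),
    "OLM":  (200.0, 200.0, 800.0),
    "NGF":  (100.0, 100.0, 400.0),
    "Ivy":  (150.0, 150.0, 600.0),
    "CA3":  (1500.0, 1500.0, 6000.0),
    "ECIII": (1500.0, 1500.0, 6000.0),
}

SYN_PER_CONN = {"Pyr": 1, "CA3": 1, "ECIII": 1, "PVB": 10, "CCKB": 8,
                "Bis": 10, "Axo": 6, "OLM": 10, "NGF": 10, "Ivy": 10, "SCA": 8}

CHANNEL = {"Pyr": "AMPA", "CA3": "AMPA", "ECIII": "AMPA",
           "PVB": "GABAA", "CCKB": "GABAA", "Bis": "GABAA", "Axo": "GABAA",
           "OLM": "GABAA", "SCA": "GABAA", "Ivy": "GABAA_slow",
           "NGF": "GABAA_slow"}

# peak conductance per synapse (nS); estimates calibrated so the driven
# reduced-scale network fires at plausible per-type rates (docs/methods.md)
WEIGHTS = {
    ("CA3", None): 0.20, ("ECIII", None): 0.20,
    ("CA3", "Pyr"): 0.08, ("ECIII", "Pyr"): 0.08,
    ("CA3", "CCKB"): 0.45, ("CA3", "Axo"): 0.06, ("CA3", "Bis"): 0.06,
    ("CA3", "Ivy"): 0.45, ("CA3", "PVB"): 0.15, ("ECIII", "NGF"): 3.50,
    ("CA3", "SCA"): 0.10, ("Pyr", "Axo"): 0.10, ("Pyr", "Bis"): 0.10,
    ("Pyr", None): 0.20, ("Pyr", "Pyr"): 0.40, ("Pyr", "OLM"): 0.015,
    ("Pyr", "PVB"): 0.08,
    ("PVB", None): 1.30, ("Axo", None): 1.00, ("Bis", None): 0.80,
    ("CCKB", None): 0.70, ("SCA", None): 0.50, ("OLM", None): 0.60,
    ("Ivy", None): 0.15, ("NGF", None): 0.005,
}
GABAB_W = 0.033  # NGF mixed synapses: GABA-B peak conductance per synapse (nS)

# postsynaptic compartment zones per presynaptic type onto pyramidal cells
ZONES_ON_PYR = {
    "Axo": ["AIS"],
    "PVB": ["soma", "proximal_dendrite_SO", "proximal_dendrite_SR"],
    "CCKB": ["soma", "proximal_dendrite_SO", "proximal_dendrite_SR"],
    "Bis": ["proximal_dendrite_SO", "proximal_dendrite_SR", "basal_dendrite"],
    "OLM": ["distal_dendrite_SLM"],
    "NGF": ["distal_dendrite_SLM"],
    "Ivy": ["proximal_dendrite_SO", "proximal_dendrite_SR"],
    "SCA": ["proximal_dendrite_SR"],
    "Pyr": ["basal_dendrite", "proximal_dendrite_SO"],
    "CA3": ["proximal_dendrite_SR", "basal_dendrite"],
    "ECIII": ["distal_dendrite_SLM"],
}
ZONES_ON_INT = ["soma", "proximal_dendrite_SR"]


def weight_for(pre, post):
    if (pre, post) in WEIGHTS:
        return WEIGHTS[(pre, post)]
    return WEIGHTS[(pre, None)]


def build_doc():
    doc = {
        "name": "ca1-full-scale",
        "seed": 1,
        "geometry": {
            "longitudinal_um": 10000.0,
            "transverse_um": 1000.0,
            "layers": {"SO": [0.0, 100.0], "SP": [100.0, 150.0],
                       "SR": [150.0, 400.0], "SLM": [400.0, 550.0]},
        },
        "cell_types": {},
        "afferents": {
            "CA3": {"count": 204700, "rate_hz": 0.65, "layer": "SR"},
            "ECIII": {"count": 250000, "rate_hz": 0.65, "layer": "SLM"},
        },
        "synapse_channels": {
            "AMPA": {"tau1_ms": 0.5, "tau2_ms": 3.0, "e_rev_mv": 0.0},
            "GABAA": {"tau1_ms": 0.3, "tau2_ms": 5.0, "e_rev_mv": -60.0},
            "GABAA_slow": {"tau1_ms": 1.0, "tau2_ms": 11.0, "e_rev_mv": -60.0},
            "GABAB": {"tau1_ms": 25.0, "tau2_ms": 100.0, "e_rev_mv": -90.0},
        },
        "axonal_profiles": {
            n: {"mean_um": m, "sd_um": s, "extent_um": e, "bin_um": 100.0}
            for n, (m, s, e) in PROFILES.items()
        },
        "neurons": {},
        "projections": {},
        "ephys_targets": {},
        "sweep_protocols": {
            n: {"hyper_pa": h, "step_pa": s, "depol_pa": d}
            for n, (h, s, d) in SWEEPS.items()
        },
    }
    for name, count in COUNTS.items():
        doc["cell_types"][name] = {
            "count": count, "layer": LAYER[name],
            "is_principal": name == "Pyr", "neuron": name,
        }
    for name, (rmp, rin, tau, rheo, thr, delay, hw) in EPHYS.items():
        dT = DELTA_T[name]
        a, b, tw, tref = ADAPT[name]
        doc["neurons"][name] = {
            "e_leak_mv": rmp, "r_in_mohm": rin, "tau_m_ms": tau,
            # AdEx steady-state rheobase g_L(V_T - dT - E_L) pinned to target
            "v_thresh_mv": round(rmp + dT + rin * rheo / 1000.0, 3),
            "delta_t_mv": dT, "v_reset_mv": rmp, "t_ref_ms": tref,
            "adapt_a_ns": a, "adapt_b_pa": b, "tau_w_ms": tw,
        }
        doc["ephys_targets"][name] = {
            "rmp_mv": rmp, "rin_mohm": rin, "tau_m_ms": tau,
            "rheobase_pa": rheo, "threshold_mv": thr,
            "delay_first_spike_ms": delay, "half_width_ms": hw,
            "threshold_anomalous": name in ANOMALOUS_THRESHOLD,
        }
    for pre, row in BUDGET.items():
        prow = {}
        for post, syn in zip(COLS, row):
            if syn <= 0:
                continue
            entry = {
                "synapses": float(syn),
                "syn_per_conn": SYN_PER_CONN[pre],
                "weight_ns": weight_for(pre, post),
                "channel": CHANNEL[pre],
                "zones": (ZONES_ON_PYR[pre] if post == "Pyr" else ZONES_ON_INT),
            }
            if pre == "NGF":
                entry["gabab_weight_ns"] = GABAB_W
            prow[post] = entry
        doc["projections"][pre] = prow
    return doc


def main():
    root = Path(__file__).resolve().parents[1]
    out = root / "src" / "ca1net" / "data" / "full_scale.yaml"
    with open(out, "w") as fh:
        fh.write("# Packaged full-scale CA1 network configuration.\n"
                 "# Census and synapse budgets are data; geometry, axonal\n"
                 "# Gaussians, kinetics and conductances are documented,\n"
                 "# configurable estimates. Regenerate: python scripts/make_config.py\n")
        yaml.safe_dump(build_doc(), fh, sort_keys=False, width=100)
    print("wrote", out)
    return 0


if __name__ == "__main__":
    sys.exit(main())
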