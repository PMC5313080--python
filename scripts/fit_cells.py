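"""Fit the reduced neuron models to their electrophysiological targets.

The passive core (resting potential, input resistance, membrane time
constant) is pinned analytically; the exponential take-off potential is
placed so the steady-state rheobase matches the target, and the spike
sharpness delta_T is grid-searched so the measured threshold (dV/dt
crossing 20 mV/ms) lands on the target threshold.  Cell types whose
printed threshold is physiologically implausible keep the default
delta_T = 2 mV.

Prints a verification table plus the fitted delta_T values; to adopt new
fits, copy them into DELTA_T in scripts/make_config.py and regenerate the
packaged configuration.

Usage: python scripts/fit_cells.py
"""

import sys
from dataclasses import replace
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from ca1net.cells import characterize, sweep_currents
from ca1net.config import default_config

GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0)


def refit(cfg, name):
    tgt = cfg.ephys_targets[name]
    base = cfg.neurons[name]
    sweep = sweep_currents(cfg.sweep_protocols[name])
    if tgt.get("threshold_anomalous"):
        return base.delta_t_mv, None
    best, best_err = base.delta_t_mv, np.inf
    for d_t in GRID:
        p = replace(base, delta_t_mv=d_t,
                    v_thresh_mv=tgt["rmp_mv"] + d_t
                    + tgt["rin_mohm"] * tgt["rheobase_pa"] / 1000.0)
        prof = characterize(p, sweep)
        err = abs(prof.threshold_mv - tgt["threshold_mv"])
        if err < best_err:
            best, best_err = d_t, err
    return best, best_err


def main():
    cfg = default_config()
    fits = {}
    print(f"{'type':6} {'dT':>4} {'thr_err':>8} | measured vs target "
          "(rmp rin tau rheo thr)")
    for name in cfg.neurons:
        d_t, err = refit(cfg, name)
        fits[name] = d_t
        tgt = cfg.ephys_targets[name]
        p = replace(cfg.neurons[name], delta_t_mv=d_t,
                    v_thresh_mv=tgt["rmp_mv"] + d_t
                    + tgt["rin_mohm"] * tgt["rheobase_pa"] / 1000.0)
        prof = characterize(p, sweep_currents(cfg.sweep_protocols[name]))
        print(f"{name:6} {d_t:4.1f} "
              f"{err if err is not None else float('nan'):8.2f} | "
              f"{prof.rmp_mv:7.1f}/{tgt['rmp_mv']:7.1f} "
              f"{prof.rin_mohm:6.1f}/{tgt['rin_mohm']:6.1f} "
              f"{prof.tau_m_ms:5.1f}/{tgt['tau_m_ms']:5.1f} "
              f"{prof.rheobase_pa:6.1f}/{tgt['rheobase_pa']:6.1f} "
              f"{prof.threshold_mv:7.1f}/{tgt['threshold_mv']:7.1f}")
    print("\nfitted DELTA_T =", fits)


if __name__ == "__main__":
    main()
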