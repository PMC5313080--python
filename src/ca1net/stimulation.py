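"""Afferent drive: Poisson and theta-modulated spike trains, and the
afferent-arithmetic estimates relating stimulating-unit activity to the
number of incoming spikes per theta cycle.

The CA1 model network is not spontaneously active; all activity is driven by
artificial stimulating units standing in for CA3 and entorhinal layer III
afferents, modelled as independent homogeneous Poisson processes.  The
phase-locked generator (inhomogeneous Poisson with a von Mises intensity) is
used for analysis fixtures and for network-clamp drive whose trains must
carry a prescribed theta modulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0, i1


@dataclass
class SpikeTrainSet:
    """Sorted spike times (ms) per afferent unit."""

    trains: list[np.ndarray]
    duration_ms: float
    seed: int | None = None

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trains))

    def as_raster(self) -> tuple[np.ndarray, np.ndarray]:
        """(unit_id, time_ms) record arrays, time-sorted."""
        if not self.trains:
            return np.empty(0, np.int64), np.empty(0)
        gid = np.concatenate([np.full(t.size, i, dtype=np.int64)
                              for i, t in enumerate(self.trains)])
        ts = np.concatenate(self.trains) if self.trains else np.empty(0)
        order = np.argsort(ts, kind="stable")
        return gid[order], ts[order]


def poisson_trains(n_units: int, rate_hz: float, duration_ms: float,
                   seed: int) -> SpikeTrainSet:
    """Independent homogeneous Poisson trains, reproducible by seed."""
    if rate_hz < 0:
        raise ValueError(f"negative rate {rate_hz}")
    rng = np.random.default_rng(seed)
    trains = []
    mean = rate_hz * duration_ms / 1000.0
    counts = rng.poisson(mean, size=n_units) if mean > 0 else np.zeros(n_units, int)
    for c in counts:
        trains.append(np.sort(rng.uniform(0.0, duration_ms, size=c)))
    return SpikeTrainSet(trains, duration_ms, seed)


def phase_locked_trains(n_units: int, mean_rate_hz: float, theta_hz: float,
                        kappa: float, preferred_phase_deg: float,
                        duration_ms: float, seed: int) -> SpikeTrainSet:
    """Inhomogeneous Poisson trains with a von Mises intensity around an
    ideal theta oscillator.

    The intensity lambda(t) = r * exp(kappa * cos(phi(t) - phi0)) / I0(kappa)
    time-averages exactly to ``mean_rate_hz``; the phase convention puts the
    oscillator trough at 0 degrees, so phi(t) = 2*pi*f*t measures phase since
    a trough.  kappa = 0 reduces to a homogeneous Poisson process.
    """
    if kappa < 0:
        raise ValueError(f"negative kappa {kappa}")
    rng = np.random.default_rng(seed)
    phi0 = np.deg2rad(preferred_phase_deg)
    lam_max = mean_rate_hz * np.exp(kappa) / i0(kappa)  # thinning envelope
    trains = []
    mean = lam_max * duration_ms / 1000.0
    for _ in range(n_units):
        c = rng.poisson(mean) if mean > 0 else 0
        t = np.sort(rng.uniform(0.0, duration_ms, size=c))
        phase = 2.0 * np.pi * theta_hz * t / 1000.0
        lam = mean_rate_hz * np.exp(kappa * np.cos(phase - phi0)) / i0(kappa)
        keep = rng.uniform(0.0, lam_max, size=c) < lam
        trains.append(t[keep])
    return SpikeTrainSet(trains, duration_ms, seed)


def expected_resultant_length(kappa: float) -> float:
    """Mean resultant length of a von Mises sample: I1(kappa)/I0(kappa)."""
    return float(i1(kappa) / i0(kappa))


def spikes_per_theta_cycle(n_afferents: int, rate_hz: float,
                           theta_hz: float) -> int:
    """Afferent spikes arriving per theta cycle, n * rate / f_theta,
    rounded to the nearest integer for reporting."""
    if theta_hz <= 0:
        raise ValueError(f"theta frequency must be positive, got {theta_hz}")
    return int(round(n_afferents * rate_hz / theta_hz))


def afferent_drive_estimate(n_cells: int, active_fraction: float,
                            spikes_per_active: float) -> int:
    """Spikes per theta cycle from an upstream area: n * fraction * spikes."""
    if not (0.0 <= active_fraction <= 1.0):
        raise ValueError(f"active fraction {active_fraction} outside [0, 1]")
    return int(round(n_cells * active_fraction * spikes_per_active))
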