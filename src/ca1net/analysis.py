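"""LFP analog and the oscillation-analysis pipeline.

Covers: the extracellular-potential proxy (inverse-distance-weighted sum of
pyramidal membrane currents around a reference electrode, with the outer
population subsampled), the spike density function (Gaussian-kernel smoothed
binned counts), Welch periodogram and spectrogram, zero-phase band filtering,
trough-referenced spike phases with Rayleigh statistics, per-type firing
rates, and theta-gamma cross-frequency coupling via the Hilbert transform.

Phase convention: the theta trough is 0/360 degrees and the peak 180 degrees,
with phase advancing linearly between consecutive troughs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

THETA_BAND = (5.0, 10.0)
GAMMA_BAND = (25.0, 80.0)
LOW_GAMMA_BAND = (25.0, 40.0)

DEFAULT_ELECTRODE_UM = (200.0, 500.0, 120.0)


@dataclass
class LfpTrace:
    fs_hz: float
    samples: np.ndarray
    electrode_um: tuple[float, float, float] = DEFAULT_ELECTRODE_UM

    @property
    def t_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs_hz * 1000.0


@dataclass
class SpectralSummary:
    freqs_hz: np.ndarray
    power: np.ndarray
    peak_hz: float
    peak_power: float

    def band_peak(self, lo_hz: float, hi_hz: float) -> tuple[float, float]:
        """(frequency, power) of the maximum inside [lo, hi]."""
        m = (self.freqs_hz >= lo_hz) & (self.freqs_hz <= hi_hz)
        if not m.any() or np.all(self.power[m] == 0):
            return float("nan"), 0.0
        k = np.argmax(self.power[m])
        return float(self.freqs_hz[m][k]), float(self.power[m][k])


@dataclass
class SpikePhaseStats:
    mean_phase_deg: float
    resultant_length: float
    rayleigh_p: float
    n_spikes: int


# ---------------------------------------------------------------------------
# LFP analog
# ---------------------------------------------------------------------------

def lfp_analog(current_traces: np.ndarray, positions_um: np.ndarray,
               electrode_um=DEFAULT_ELECTRODE_UM, fs_hz: float = 1000.0,
               inner_radius_um: float = 100.0, outer_fraction: float = 0.1,
               rng: np.random.Generator | None = None,
               min_distance_um: float = 10.0) -> LfpTrace:
    """Point-source extracellular-potential proxy.

    Every cell within ``inner_radius_um`` of the electrode contributes its
    membrane current scaled in inverse proportion to its distance; a random
    ``outer_fraction`` of the remaining cells is sampled and each sampled
    contribution is scaled up by 1/outer_fraction, an unbiased estimator of
    the full outer sum.  The conductivity constant is absorbed into the
    arbitrary output scale; distances are floored at ``min_distance_um``.
    """
    traces = np.atleast_2d(np.asarray(current_traces, dtype=float))
    pos = np.atleast_2d(np.asarray(positions_um, dtype=float))
    if traces.shape[0] == 0:
        return LfpTrace(fs_hz, np.zeros(0 if traces.ndim < 2 else traces.shape[1]),
                        tuple(electrode_um))
    d = np.linalg.norm(pos - np.asarray(electrode_um), axis=1)
    d = np.maximum(d, min_distance_um)
    inner = d <= inner_radius_um
    weights = np.where(inner, 1.0 / d, 0.0)
    outer_idx = np.nonzero(~inner)[0]
    if outer_idx.size and outer_fraction > 0:
        rng = rng or np.random.default_rng(0)
        k = int(round(outer_fraction * outer_idx.size))
        if k > 0:
            pick = rng.choice(outer_idx, size=k, replace=False)
            weights[pick] = (1.0 / d[pick]) / outer_fraction
    return LfpTrace(fs_hz, weights @ traces, tuple(electrode_um))


# ---------------------------------------------------------------------------
# Spike density function and spectra
# ---------------------------------------------------------------------------

def sdf(spike_times_ms: np.ndarray, duration_ms: float, bin_ms: float = 1.0,
        kernel_sd_ms: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Spike density function: binned counts convolved with a unit-mass
    Gaussian kernel (SD ``kernel_sd_ms``, truncated at 3 SD), edge-corrected
    so the series integrates exactly to the spike count.

    Returns (bin centres in ms, rate in spikes/s).
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    n_bins = int(round(duration_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    counts, _ = np.histogram(np.asarray(spike_times_ms), bins=edges)
    half = max(1, int(math.ceil(3.0 * kernel_sd_ms / bin_ms)))
    x = np.arange(-half, half + 1) * bin_ms
    kern = np.exp(-0.5 * (x / kernel_sd_ms) ** 2)
    kern /= kern.sum()
    # edge correction: a spike near the border keeps unit mass by scaling
    # its kernel by the mass that falls inside the window
    mass = np.convolve(np.ones(n_bins), kern, mode="same")
    smooth = np.convolve(counts / mass, kern, mode="same")
    centres = edges[:-1] + 0.5 * bin_ms
    return centres, smooth * (1000.0 / bin_ms)


def welch_psd(series: np.ndarray, fs_hz: float, segment_ms: float = 1024.0,
              overlap: float = 0.5) -> SpectralSummary:
    """One-sided Welch periodogram with a Hamming window and 50% overlap."""
    series = np.asarray(series, dtype=float)
    nperseg = int(round(segment_ms * fs_hz / 1000.0))
    if series.size < nperseg:
        raise ValueError("series shorter than one Welch segment")
    f, p = signal.welch(series - series.mean(), fs=fs_hz, window="hamming",
                        nperseg=nperseg, noverlap=int(nperseg * overlap))
    k = int(np.argmax(p))
    return SpectralSummary(f, p, float(f[k]), float(p[k]))


def spectrogram(series: np.ndarray, fs_hz: float, window_ms: float = 1024.0,
                step_ms: float = 128.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window PSD; returns (t_s, f_hz, power[f, t])."""
    series = np.asarray(series, dtype=float)
    nperseg = int(round(window_ms * fs_hz / 1000.0))
    if series.size < nperseg:
        raise ValueError("window exceeds series length")
    step = int(round(step_ms * fs_hz / 1000.0))
    f, t, s = signal.spectrogram(series - series.mean(), fs=fs_hz,
                                 window="hamming", nperseg=nperseg,
                                 noverlap=nperseg - step)
    return t, f, s


def bandpass(series: np.ndarray, fs_hz: float, lo_hz: float, hi_hz: float,
             order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    if not (0.0 < lo_hz < hi_hz < fs_hz / 2.0):
        raise ValueError(f"invalid band ({lo_hz}, {hi_hz}) at fs {fs_hz}")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs_hz,
                        output="sos")
    return signal.sosfiltfilt(sos, np.asarray(series, dtype=float))


# ---------------------------------------------------------------------------
# Spike phases and circular statistics
# ---------------------------------------------------------------------------

def find_troughs(theta_filtered: np.ndarray, fs_hz: float,
                 min_separation_ms: float = 50.0) -> np.ndarray:
    """Indices of local minima of the theta-filtered trace."""
    dist = max(1, int(round(min_separation_ms * fs_hz / 1000.0)))
    troughs, _ = signal.find_peaks(-np.asarray(theta_filtered), distance=dist)
    return troughs


def spike_phases(spike_times_ms: np.ndarray, theta_filtered: np.ndarray,
                 fs_hz: float, crop_ms: float = 50.0) -> np.ndarray:
    """Theta phase (deg) of each spike, trough-referenced.

    Phase advances linearly from 0 to 360 degrees between consecutive troughs
    of the filtered trace; spikes before the first trough, after the last
    trough, or within the first ``crop_ms`` of the simulation are discarded.
    """
    troughs = find_troughs(theta_filtered, fs_hz)
    if troughs.size < 2:
        raise ValueError("no theta troughs found")
    trough_t = troughs / fs_hz * 1000.0
    t = np.asarray(spike_times_ms, dtype=float)
    t = t[t >= crop_ms]
    inside = (t >= trough_t[0]) & (t < trough_t[-1])
    t = t[inside]
    idx = np.searchsorted(trough_t, t, side="right") - 1
    t0, t1 = trough_t[idx], trough_t[idx + 1]
    return 360.0 * (t - t0) / (t1 - t0)


def phase_stats(phases_deg: np.ndarray) -> SpikePhaseStats:
    """Circular mean, resultant length and Rayleigh test of spike phases."""
    ph = np.deg2rad(np.asarray(phases_deg, dtype=float))
    n = ph.size
    if n == 0:
        raise ValueError("no spike phases")
    c, s = np.cos(ph).sum(), np.sin(ph).sum()
    r = math.hypot(c, s) / n
    mean = math.degrees(math.atan2(s, c)) % 360.0
    big_r = n * r
    # Rayleigh p approximation (Zar); accurate for all n
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - big_r * big_r))
                 - (1.0 + 2.0 * n))
    return SpikePhaseStats(mean, r, min(p, 1.0), n)


def firing_rates(spike_times_ms: np.ndarray, n_total: int, duration_ms: float,
                 spike_gids: np.ndarray | None = None,
                 crop_ms: float = 50.0) -> tuple[float, float]:
    """(rate over all cells, rate over active cells), in Hz.

    The first ``crop_ms`` of the simulation is discarded; a cell is active if
    it fires at least once afterwards.  With no active cells the per-active
    rate is nan.
    """
    if duration_ms <= crop_ms:
        raise ValueError("duration must exceed the cropped interval")
    t = np.asarray(spike_times_ms)
    keep = t >= crop_ms
    n_spikes = int(keep.sum())
    dur_s = (duration_ms - crop_ms) / 1000.0
    rate_all = n_spikes / (n_total * dur_s) if n_total else 0.0
    if spike_gids is not None:
        n_active = np.unique(np.asarray(spike_gids)[keep]).size
    else:
        n_active = 1 if n_spikes else 0
    rate_active = n_spikes / (n_active * dur_s) if n_active else float("nan")
    return rate_all, rate_active


# ---------------------------------------------------------------------------
# Cross-frequency coupling
# ---------------------------------------------------------------------------

def cross_frequency_coupling(lfp: LfpTrace, theta_band=THETA_BAND,
                             gamma_band=GAMMA_BAND, bin_deg: float = 20.0
                             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean gamma envelope as a function of theta phase.

    Both bands are filtered zero-phase, the Hilbert transform supplies the
    theta phase (trough-referenced: -pi at the filtered minimum maps to 0/360
    degrees) and the gamma amplitude envelope.  Returns (bin centres in deg,
    mean envelope per bin, phase of the maximal envelope).
    """
    theta = bandpass(lfp.samples, lfp.fs_hz, *theta_band)
    gamma = bandpass(lfp.samples, lfp.fs_hz, *gamma_band)
    # analytic phase is 0 at the oscillation peak; shift so troughs sit at 0
    phase = (np.angle(signal.hilbert(theta)) + np.pi) % (2 * np.pi)
    env = np.abs(signal.hilbert(gamma))
    edges = np.arange(0.0, 360.0 + bin_deg, bin_deg)
    centres = edges[:-1] + bin_deg / 2.0
    deg = np.rad2deg(phase)
    idx = np.clip(np.digitize(deg, edges) - 1, 0, centres.size - 1)
    profile = np.array([env[idx == k].mean() if (idx == k).any() else 0.0
                        for k in range(centres.size)])
    return centres, profile, float(centres[int(np.argmax(profile))])
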