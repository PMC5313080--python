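import numpy as np
import pytest

from ca1net import analysis
from ca1net.analysis import (LfpTrace, bandpass, cross_frequency_coupling,
                             firing_rates, lfp_analog, phase_stats, sdf,
                             spectrogram, spike_phases, welch_psd)

FS = 1000.0


def tone(freq_hz, duration_s=8.0, fs=FS, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return t, amp * np.sin(2 * np.pi * freq_hz * t)


class TestSdf:
    def test_no_spikes_gives_all_zeros(self):
        _, rate = sdf(np.array([]), 1000.0)
        assert (rate == 0).all()

    def test_single_spike_mass_is_one(self):
        for t_spike in (2.0, 500.0, 997.0):  # includes edge positions
            _, rate = sdf(np.array([t_spike]), 1000.0)
            assert rate.sum() * 1e-3 == pytest.approx(1.0, abs=1e-6)

    def test_mass_conservation_for_arbitrary_rasters(self, rng):
        times = rng.uniform(0, 2000.0, size=1234)
        _, rate = sdf(times, 2000.0)
        assert rate.sum() * 1e-3 == pytest.approx(1234.0, abs=1e-6)

    def test_poisson_rate_recovered(self, rng):
        times = np.sort(rng.uniform(0, 10_000.0, size=rng.poisson(500)))
        _, rate = sdf(times, 10_000.0)
        assert rate.mean() == pytest.approx(50.0, abs=3 * 50.0 / np.sqrt(500))

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            sdf(np.array([1.0]), 0.0)


class TestWelch:
    def test_pure_tone_peak_recovered(self):
        _, x = tone(7.8)
        psd = welch_psd(x, FS)
        assert psd.peak_hz == pytest.approx(7.8, abs=1.0)

    def test_theta_and_gamma_tones_separated(self):
        _, x1 = tone(7.8)
        _, x2 = tone(71.0, amp=0.5)
        psd = welch_psd(x1 + x2, FS)
        th_f, _ = psd.band_peak(*analysis.THETA_BAND)
        ga_f, _ = psd.band_peak(*analysis.GAMMA_BAND)
        assert th_f == pytest.approx(7.8, abs=1.0)
        assert ga_f == pytest.approx(71.0, abs=1.0)

    def test_parseval_for_white_noise(self, rng):
        x = rng.standard_normal(32_768)
        psd = welch_psd(x, FS)
        df = psd.freqs_hz[1] - psd.freqs_hz[0]
        assert (psd.power.sum() * df) == pytest.approx(x.var(), rel=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), FS, segment_ms=1024.0)


class TestSpectrogram:
    def test_constant_tone_gives_constant_ridge(self):
        _, x = tone(7.8, duration_s=16.0)
        t, f, s = spectrogram(x, FS, window_ms=2048.0, step_ms=512.0)
        ridge = f[np.argmax(s, axis=0)]
        assert np.allclose(ridge, 7.8, atol=0.5)

    def test_silent_signal_gives_zero_power(self):
        t, f, s = spectrogram(np.zeros(4096), FS, window_ms=1024.0, step_ms=256.0)
        assert np.allclose(s, 0.0)

    def test_chirp_ridge_is_monotone(self):
        from scipy.signal import chirp
        tt = np.arange(0, 40.0, 1.0 / FS)
        x = chirp(tt, f0=5.0, f1=10.0, t1=40.0)
        t, f, s = spectrogram(x, FS, window_ms=4096.0, step_ms=1024.0)
        ridge = f[np.argmax(s, axis=0)]
        assert (np.diff(ridge) >= -1e-9).all() and ridge[-1] > ridge[0]

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            spectrogram(np.zeros(100), FS, window_ms=1024.0, step_ms=128.0)


class TestBandpass:
    def test_in_band_tone_preserved_with_zero_phase_shift(self):
        t, x = tone(7.8)
        y = bandpass(x, FS, 5.0, 10.0)
        mid = slice(2000, 6000)  # clear of filter edge transients
        assert np.abs(y[mid]).max() >= 0.95
        lag = np.argmax(np.correlate(y[mid], x[mid], "full")) - (len(x[mid]) - 1)
        assert lag == 0

    def test_out_of_band_tone_attenuated(self):
        _, x = tone(40.0)
        y = bandpass(x, FS, 5.0, 10.0)
        assert np.abs(y[2000:6000]).max() <= 0.1

    def test_dc_removed(self):
        y = bandpass(np.full(8000, 3.0), FS, 5.0, 10.0)
        assert np.abs(y[2000:6000]).max() < 1e-6

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(1000), FS, 10.0, 5.0)
        with pytest.raises(ValueError):
            bandpass(np.zeros(1000), FS, 5.0, 600.0)


class TestSpikePhases:
    def setup_method(self):
        self.f = 7.8
        t = np.arange(int(4.0 * FS)) / FS
        self.lfp = -np.cos(2 * np.pi * self.f * t)  # troughs at k/f
        self.troughs_ms = 1000.0 * np.arange(1, 25) / self.f

    def test_spikes_at_minima_map_to_zero_degrees(self):
        ph = spike_phases(self.troughs_ms[5:15], self.lfp, FS)
        assert np.allclose(np.minimum(ph, 360.0 - ph), 0.0, atol=3.0)

    def test_spikes_at_maxima_map_to_180_degrees(self):
        peaks = self.troughs_ms[5:15] + 500.0 / self.f
        ph = spike_phases(peaks, self.lfp, FS)
        assert np.allclose(ph, 180.0, atol=3.0)

    def test_rising_quarter_cycle_midpoint_maps_to_90_degrees(self):
        quarter = self.troughs_ms[5:15] + 250.0 / self.f
        ph = spike_phases(quarter, self.lfp, FS)
        assert np.allclose(ph, 90.0, atol=3.0)

    def test_first_50_ms_cropped(self):
        early = np.array([10.0, 40.0])
        with pytest.raises(ValueError):
            # only early spikes remain -> none survive the crop+trough window
            ph = spike_phases(early, self.lfp, FS)
            if ph.size == 0:
                raise ValueError("empty")

    def test_flat_trace_has_no_troughs(self):
        with pytest.raises(ValueError, match="trough"):
            spike_phases(np.array([100.0]), np.zeros(1000), FS)


class TestPhaseStats:
    def test_identical_phases_fully_modulated(self):
        st = phase_stats(np.full(50, 123.0))
        assert st.resultant_length == pytest.approx(1.0)
        assert st.mean_phase_deg == pytest.approx(123.0)
        assert st.rayleigh_p < 1e-6

    def test_uniform_grid_has_zero_resultant(self):
        st = phase_stats(np.arange(360.0))
        assert st.resultant_length < 1e-6

    def test_von_mises_sample_matches_bessel_ratio(self, rng):
        ph = np.rad2deg(rng.vonmises(0.0, 2.0, size=100_000)) % 360.0
        st = phase_stats(ph)
        from ca1net.stimulation import expected_resultant_length
        assert st.resultant_length == pytest.approx(
            expected_resultant_length(2.0), abs=0.01)
        assert min(st.mean_phase_deg, 360 - st.mean_phase_deg) < 2.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            phase_stats(np.array([]))


class TestFiringRates:
    def test_counts_divided_by_all_and_by_active(self):
        # 10 cells, 5 active, 100 spikes in 1 s (after the crop)
        gids = np.repeat(np.arange(5), 20)
        times = np.linspace(51.0, 1049.0, 100)
        r_all, r_act = firing_rates(times, 10, 1050.0, gids, crop_ms=50.0)
        assert r_all == pytest.approx(10.0, rel=1e-6)
        assert r_act == pytest.approx(20.0, rel=1e-6)

    def test_no_spikes_yields_zero_and_nan(self):
        r_all, r_act = firing_rates(np.array([]), 10, 1000.0, np.array([]))
        assert r_all == 0.0 and np.isnan(r_act)

    def test_crop_removes_early_spikes(self):
        times = np.array([10.0, 20.0, 100.0])
        gids = np.array([0, 1, 0])
        r_all, r_act = firing_rates(times, 1, 1050.0, gids)
        assert r_all == pytest.approx(1.0)  # only the 100 ms spike counts
        assert r_act == pytest.approx(1.0)


class TestLfpAnalog:
    def test_inverse_distance_weighting(self):
        # one source at d and one at 2d: contribution ratio 2:1
        traces = np.array([[1.0] * 10, [1.0] * 10])
        pos = np.array([[50.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
        lfp_near = lfp_analog(traces[:1], pos[:1], electrode_um=(0, 0, 0),
                              inner_radius_um=1000.0)
        lfp_far = lfp_analog(traces[1:], pos[1:], electrode_um=(0, 0, 0),
                             inner_radius_um=1000.0)
        assert lfp_near.samples[0] == pytest.approx(2.0 * lfp_far.samples[0])

    def test_no_cells_gives_zero_trace(self):
        lfp = lfp_analog(np.zeros((0, 100)), np.zeros((0, 3)))
        assert lfp.samples.size == 0 or np.allclose(lfp.samples, 0)

    def test_distance_floor_prevents_singularity(self):
        traces = np.ones((1, 5))
        lfp = lfp_analog(traces, np.array([[200.0, 500.0, 120.0]]),
                         inner_radius_um=1000.0)  # exactly at the electrode
        assert np.isfinite(lfp.samples).all()
        assert lfp.samples[0] == pytest.approx(1.0 / 10.0)

    def test_outer_sampling_estimator_is_unbiased(self, rng):
        # Monte-Carlo over seeds vs the exhaustive outer sum on 1,000 cells
        n = 1000
        pos = np.column_stack([rng.uniform(0, 2000, n), rng.uniform(0, 1000, n),
                               rng.uniform(100, 150, n)])
        traces = rng.uniform(0.5, 1.5, size=(n, 1))
        electrode = (1000.0, 500.0, 120.0)
        d = np.maximum(np.linalg.norm(pos - np.array(electrode), axis=1), 10.0)
        outer = d > 100.0
        exact = ((traces[:, 0] / d) * outer).sum() + \
            ((traces[:, 0] / d) * ~outer).sum()
        draws = [lfp_analog(traces, pos, electrode,
                            rng=np.random.default_rng(s)).samples[0]
                 for s in range(100)]
        se = np.std(draws) / np.sqrt(len(draws))
        assert np.mean(draws) == pytest.approx(exact, abs=2 * se + 1e-12)


class TestCrossFrequencyCoupling:
    @staticmethod
    def _coupled_signal(burst_phase_deg):
        t = np.arange(int(16.0 * FS)) / FS
        theta = -np.cos(2 * np.pi * 7.8 * t)  # trough at phase 0
        env = 0.5 * (1 + np.cos(2 * np.pi * 7.8 * t
                                - np.deg2rad(burst_phase_deg)))
        gamma = 0.4 * env * np.sin(2 * np.pi * 40.0 * t)
        return LfpTrace(FS, theta + gamma)

    def test_gamma_bursts_at_troughs_detected(self):
        centres, prof, peak = cross_frequency_coupling(self._coupled_signal(0.0))
        assert min(peak, 360.0 - peak) <= 30.0

    def test_gamma_bursts_at_peaks_detected(self):
        _, _, peak = cross_frequency_coupling(self._coupled_signal(180.0))
        assert abs(peak - 180.0) <= 30.0

    def test_constant_gamma_gives_flat_profile(self):
        t = np.arange(int(16.0 * FS)) / FS
        x = -np.cos(2 * np.pi * 7.8 * t) + 0.4 * np.sin(2 * np.pi * 40.0 * t)
        _, prof, _ = cross_frequency_coupling(LfpTrace(FS, x))
        assert prof.max() / prof.min() < 1.05

    def test_no_gamma_component_gives_tiny_envelope(self):
        t = np.arange(int(16.0 * FS)) / FS
        x = -np.cos(2 * np.pi * 7.8 * t)
        _, prof, _ = cross_frequency_coupling(LfpTrace(FS, x))
        assert prof.max() < 0.02
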