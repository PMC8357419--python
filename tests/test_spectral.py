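import numpy as np
import pytest
from scipy import signal as sps

from spindlekit.spectral import (
    aperiodic_exponent,
    detect_oscillatory_epochs,
    gabor_spectrogram,
    spectrogram_band_power,
    twitch_event_xcorr,
    twitch_triggered_spectrogram,
    whiten_ar1,
)
from spindlekit.synth import pink_noise

from conftest import tukey_burst


class TestWhiten:
    def test_white_noise_phi_near_zero(self, rng):
        x = rng.standard_normal(50000)
        y, phi = whiten_ar1(x)
        assert abs(phi) < 0.02
        assert np.corrcoef(x, y)[0, 1] > 0.99

    def test_ar1_coefficient_recovered(self, rng):
        """Yule-Walker oracle: phi estimated from a phi=0.9 AR(1) process."""
        n = 100_000
        e = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = e[0]
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + e[i]
        y, phi = whiten_ar1(x)
        assert phi == pytest.approx(0.9, abs=0.02)
        # residual lag-1 autocorrelation vanishes
        yc = y - y.mean()
        assert abs((yc[1:] @ yc[:-1]) / (yc @ yc)) < 0.02

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            whiten_ar1(np.full(100, 3.0))


class TestGaborSpectrogram:
    def test_tone_localized_to_nearest_grid_row(self):
        fs = 500.0
        t = np.arange(0, 10, 1 / fs)
        ws = gabor_spectrogram(np.sin(2 * np.pi * 15 * t), fs)
        row = ws.magnitude[:, int(2 * fs) : -int(2 * fs)].mean(axis=1).argmax()
        nearest = np.argmin(np.abs(ws.freqs - 15))
        assert row == nearest

    def test_two_tones_two_maxima(self):
        fs = 500.0
        t = np.arange(0, 10, 1 / fs)
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 60 * t)
        ws = gabor_spectrogram(x, fs)
        prof = ws.magnitude[:, int(fs) : -int(fs)].mean(axis=1)
        peaks, _ = sps.find_peaks(prof, prominence=0.3)
        found = sorted(ws.freqs[p] for p in peaks)
        assert len(found) == 2
        assert abs(found[0] - 10) < 1.5 and abs(found[1] - 60) < 5

    def test_chirp_ridge_increases(self):
        fs = 500.0
        t = np.arange(0, 20, 1 / fs)
        x = sps.chirp(t, f0=5, f1=40, t1=20)
        ws = gabor_spectrogram(x, fs, np.geomspace(3, 60, 40))
        mid = ws.magnitude[:, int(2 * fs) : -int(2 * fs)]
        ridge = ws.freqs[mid.argmax(axis=0)]
        smooth = np.convolve(ridge, np.ones(500) / 500, mode="valid")
        assert (np.diff(smooth[:: int(fs)]) > -0.5).all()
        assert smooth[-1] > smooth[0] + 20

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            gabor_spectrogram(np.zeros(1000), 500.0, np.array([]))

    def test_wavelet_power_consistent_with_variance(self, rng):
        """Parseval-style check: integrated wavelet PSD ~ band variance."""
        fs = 1250.0
        x = pink_noise(int(20 * fs), fs, 1.0, 10.0, rng)
        ws = gabor_spectrogram(x, fs)
        wp = spectrogram_band_power(ws, (2, 80))
        sos = sps.butter(4, [2, 80], btype="bandpass", fs=fs, output="sos")
        v = np.var(sps.sosfiltfilt(sos, x))
        assert abs(wp / v - 1) < 0.15


class TestOscillatoryEpochs:
    def test_single_burst_recovered_with_tight_boundaries(self, rng):
        fs = 1250.0
        x = 3.0 * rng.standard_normal(int(30 * fs))
        x[int(10 * fs) : int(11 * fs)] += tukey_burst(12.0, 1.0, fs, 30.0)
        ep = detect_oscillatory_epochs(x, fs)
        assert len(ep.intervals) == 1
        a, b = ep.intervals[0]
        assert abs(a - 10.0) < 0.1 and abs(b - 11.0) < 0.1

    def test_stationary_noise_yields_almost_no_epochs(self):
        total = 0.0
        for seed in range(3):
            x = np.random.default_rng(seed).standard_normal(int(30 * 1250))
            total += detect_oscillatory_epochs(x, 1250.0).total_duration
        assert total / 90.0 <= 0.02

    def test_duration_summaries(self, rng):
        fs = 1250.0
        x = 3.0 * rng.standard_normal(int(30 * fs))
        x[int(8 * fs) : int(9 * fs)] += tukey_burst(12.0, 1.0, fs, 30.0)
        x[int(15 * fs) : int(17 * fs)] += tukey_burst(12.0, 2.0, fs, 30.0)
        ep = detect_oscillatory_epochs(x, fs)
        assert ep.total_duration == pytest.approx(3.0, abs=0.3)
        assert ep.mean_duration == pytest.approx(1.5, abs=0.15)

    def test_amplitude_equivariance(self, rng):
        """Scaling the signal scales the threshold; epochs are unchanged."""
        fs = 1250.0
        x = 3.0 * rng.standard_normal(int(30 * fs))
        x[int(10 * fs) : int(11 * fs)] += tukey_burst(12.0, 1.0, fs, 30.0)
        e1 = detect_oscillatory_epochs(x, fs)
        e2 = detect_oscillatory_epochs(7.0 * x, fs)
        assert e2.threshold == pytest.approx(7.0 * e1.threshold, rel=1e-9)
        assert e1.intervals == e2.intervals

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError):
            detect_oscillatory_epochs(np.zeros(1000), 1250.0)


class TestTwitchTriggered:
    def make_coupled(self, rng, fs=500.0, dur=120.0, lag=0.3):
        x = pink_noise(int(dur * fs), fs, 1.0, 10.0, rng)
        twitches = np.arange(5.0, dur - 5.0, 2.2)
        for t in twitches:
            i = int((t + lag) * fs)
            burst = tukey_burst(14.0, 0.4, fs, 60.0, taper=0.2)
            x[i : i + burst.size] += burst
        return x, twitches

    def test_locked_events_show_positive_z_at_lag(self, rng):
        fs = 500.0
        x, twitches = self.make_coupled(rng, fs=fs)
        ws = gabor_spectrogram(x, fs, np.geomspace(2, 80, 30), whiten=True)
        avg, lags = twitch_triggered_spectrogram(ws, twitches, window=1.0)
        rows = (ws.freqs >= 10) & (ws.freqs <= 20)
        at_lag = avg[rows, np.argmin(np.abs(lags - 0.4))].mean()
        assert at_lag > 1.0

    def test_coincident_power_zeroed(self, rng):
        fs = 500.0
        x, twitches = self.make_coupled(rng, fs=fs)
        ws = gabor_spectrogram(x, fs, np.geomspace(2, 80, 10))
        avg, lags = twitch_triggered_spectrogram(ws, twitches, window=1.0, zero_window=0.05)
        assert np.all(avg[:, np.abs(lags) <= 0.05] == 0)

    def test_shuffled_twitches_flat(self, rng):
        fs = 500.0
        x, _ = self.make_coupled(rng, fs=fs)
        ws = gabor_spectrogram(x, fs, np.geomspace(2, 80, 20), whiten=True)
        shuffled = np.sort(np.random.default_rng(0).uniform(2, 118, 50))
        avg, _ = twitch_triggered_spectrogram(ws, shuffled, window=1.0)
        assert np.abs(avg).max() < 0.5

    def test_edge_twitch_excluded_and_error_when_none_left(self):
        ws = gabor_spectrogram(np.random.default_rng(0).standard_normal(5000), 500.0, np.geomspace(2, 40, 5))
        with pytest.raises(ValueError):
            twitch_triggered_spectrogram(ws, np.array([0.1]), window=1.0)


class TestTwitchEventXcorr:
    def test_shifted_events_flagged_at_lag(self):
        twitches = np.arange(5.0, 115.0, 2.0)
        xc = twitch_event_xcorr(twitches, twitches + 0.2, lag_range=1.0, bin_width=0.1, n_shuffle=200, seed=0)
        flagged = xc.lags[xc.exceeds & (xc.counts > xc.ci_high)]
        assert any(abs(l - 0.25) < 0.11 or abs(l - 0.15) < 0.11 for l in flagged)

    def test_independent_series_rarely_flagged(self):
        fracs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            tw = np.sort(r.uniform(0, 300, 80))
            ev = np.sort(r.uniform(0, 300, 100))
            xc = twitch_event_xcorr(tw, ev, lag_range=1.0, bin_width=0.1, n_shuffle=200, seed=seed)
            fracs.append(xc.exceeds.mean())
        assert np.mean(fracs) <= 0.07

    def test_zero_shuffles_rejected(self):
        with pytest.raises(ValueError):
            twitch_event_xcorr(np.array([1.0]), np.array([2.0]), n_shuffle=0)


class TestAperiodicFit:
    def test_exact_power_laws(self):
        f = np.linspace(1, 60, 200)
        assert aperiodic_exponent(f, f ** -2.0).exponent == pytest.approx(2.0, abs=0.05)
        assert aperiodic_exponent(f, np.ones_like(f)).exponent == pytest.approx(0.0, abs=0.05)

    def test_narrowband_peak_masked(self):
        f = np.linspace(1, 60, 200)
        p = f ** -1.5 * (1 + 20 * np.exp(-((f - 12) ** 2) / 2))
        fit = aperiodic_exponent(f, p)
        assert fit.exponent == pytest.approx(1.5, abs=0.1)
        assert fit.masked.any()

    def test_nonpositive_power_rejected(self):
        f = np.linspace(2, 40, 50)
        p = f ** -1.0
        p[10] = 0.0
        with pytest.raises(ValueError):
            aperiodic_exponent(f, p)
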