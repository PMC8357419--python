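import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spindlekit.spikes import (
    SpikeTrain,
    autocorrelogram_ci,
    deduplicate,
    detect_spikes,
    event_triggered_rate,
    isi,
    phase_locking,
    rayleigh_p,
    vonmises_kappa_mle,
)
from spindlekit.synth import SynthEvent, SynthLFPSpec, SynthSpikesSpec, generate_lfp, generate_spikes


def poisson_train(rate, duration, seed, zone="deep-A"):
    r = np.random.default_rng(seed)
    t = np.sort(r.uniform(0, duration, r.poisson(rate * duration)))
    return SpikeTrain(times=t, zone=zone)


class TestDetection:
    def test_injected_spikes_recovered(self):
        rec, truth = generate_lfp(SynthLFPSpec(n_channels=2, fs=20000.0, duration=25.0), seed=3)
        spec = SynthSpikesSpec(baseline_rate=10.0, amplitude_factor=8.0, zones={0: "deep-A", 1: "superficial"})
        st_truth = generate_spikes(spec, rec, truth, seed=4)
        trains = detect_spikes(rec.signal, rec.fs, [(0.0, 0.0), (0.0, 800.0)], spec.zones)
        gt = st_truth[st_truth.zone == "deep-A"].time_s.to_numpy()
        det = trains["deep-A"].times
        recall = np.mean([np.min(np.abs(det - t)) < 0.002 for t in gt])
        precision = np.mean([np.min(np.abs(gt - t)) < 0.002 for t in det])
        assert recall >= 0.95 and precision >= 0.95

    def test_distant_coincident_artifacts_removed_everywhere(self):
        fs = 20000.0
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, int(2 * fs)))
        # same-time large negative transient on channels 400 um apart
        i = int(1.0 * fs)
        x[:, i - 3 : i + 3] -= 40.0
        trains = detect_spikes(x, fs, [(0.0, 0.0), (0.0, 400.0)], {0: "deep-A", 1: "deep-B"}, prefiltered=True)
        for tr in trains.values():
            assert not np.any(np.abs(tr.times - 1.0) < 0.002)

    def test_within_zone_duplicates_keep_first(self):
        t = deduplicate(np.array([1.000, 1.001, 1.005]))
        assert t.tolist() == [1.000, 1.005]

    def test_unassigned_zones_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros((1, 1000)), 20000.0, [(0, 0)], {})

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=50))
    def test_dedup_idempotent(self, times):
        once = deduplicate(np.array(times))
        twice = deduplicate(once)
        assert np.array_equal(once, twice)


class TestISI:
    def test_known_intervals(self):
        tr = SpikeTrain(times=np.array([0.0, 0.1, 0.3]), zone="z")
        assert np.allclose(isi(tr), [0.1, 0.2])

    def test_poisson_mean_isi(self):
        tr = poisson_train(10.0, 1000.0, seed=0)
        assert np.mean(isi(tr)) == pytest.approx(0.1, rel=0.05)

    def test_matches_bruteforce_differencing(self):
        tr = poisson_train(5.0, 50.0, seed=1)
        assert np.array_equal(isi(tr), np.diff(np.sort(tr.times)))

    def test_single_spike_rejected(self):
        with pytest.raises(ValueError):
            isi(SpikeTrain(times=np.array([1.0]), zone="z"))


class TestAutocorrelogram:
    def test_poisson_coverage_calibrated(self):
        """~5% of bins fall outside the 95% convolution band on Poisson trains."""
        fracs = []
        for seed in range(10):
            acg = autocorrelogram_ci(poisson_train(5.0, 400.0, seed))
            out = (acg.counts > acg.ci_high) | (acg.counts < acg.ci_low)
            out[np.argmin(np.abs(acg.lags))] = False
            fracs.append(out.mean())
        assert abs(np.mean(fracs) - 0.05) <= 0.03

    def test_doublet_train_flags_burst_excess(self):
        r = np.random.default_rng(1)
        base = np.sort(r.uniform(0, 100, 800))
        tr = SpikeTrain(times=np.sort(np.concatenate([base, base + 0.005])), zone="z")
        acg = autocorrelogram_ci(tr)
        assert acg.burst_excess > 0

    def test_symmetry_about_zero_lag(self):
        acg = autocorrelogram_ci(poisson_train(8.0, 100.0, seed=2))
        assert np.array_equal(acg.counts, acg.counts[::-1])

    def test_too_few_spikes_rejected(self):
        with pytest.raises(ValueError):
            autocorrelogram_ci(SpikeTrain(times=np.arange(10) * 0.1, zone="z"))


class TestEventTriggeredRate:
    def make_modulated(self, gain, seed):
        events = [SynthEvent(onset=2.0 + 5 * k, duration=1.5, freq=12.0, amplitude=100.0) for k in range(100)]
        rec, truth = generate_lfp(SynthLFPSpec(duration=510.0, fs=250.0, events=events), seed=seed)
        spec = SynthSpikesSpec(baseline_rate=6.0, event_gain=gain, zones={0: "deep-A"})
        spikes = generate_spikes(spec, rec, truth, seed=seed + 1, inject=False)
        tr = SpikeTrain(times=np.sort(spikes.time_s.to_numpy()), zone="deep-A")
        return tr, truth.start_s.to_numpy()

    def test_gain_plateau_recovered(self):
        tr, onsets = self.make_modulated(3.0, seed=10)
        psth = event_triggered_rate(tr, onsets, seed=0)
        during = (psth.lags > 0.2) & (psth.lags < 1.2)
        assert psth.rate[during].mean() == pytest.approx(3.0, abs=0.3)

    def test_unmodulated_train_within_ci(self):
        tr, onsets = self.make_modulated(1.0, seed=20)
        psth = event_triggered_rate(tr, onsets, seed=0)
        inside = (psth.rate >= psth.ci_low) & (psth.rate <= psth.ci_high)
        assert inside.mean() >= 0.9

    def test_zero_baseline_flagged(self):
        # all spikes inside events, none in the baseline window
        tr = SpikeTrain(times=np.array([10.1, 10.2, 20.1, 20.2, 30.1, 30.15, 40.1, 50.1]), zone="z")
        psth = event_triggered_rate(tr, np.array([10.0, 20.0, 30.0, 40.0, 50.0]), seed=0)
        assert psth.undefined


class TestPhaseLocking:
    def test_kappa_recovered_from_signal(self):
        events = [SynthEvent(onset=2.0 + 5 * k, duration=1.5, freq=12.0, amplitude=100.0) for k in range(40)]
        rec, truth = generate_lfp(SynthLFPSpec(duration=210.0, events=events), seed=5)
        spec = SynthSpikesSpec(baseline_rate=4.0, event_gain=4.0, kappa=5.0, preferred_phase=np.pi, zones={0: "deep-A"})
        spikes = generate_spikes(spec, rec, truth, seed=6, inject=False)
        tr = SpikeTrain(times=np.sort(spikes[spikes.in_event].time_s.to_numpy()), zone="deep-A")
        res = phase_locking(tr, rec.signal[0], rec.fs, list(zip(truth.start_s, truth.end_s)))
        assert abs(res.kappa - 5.0) / 5.0 < 0.2
        assert res.significant
        # locked to the trough of the band-passed waveform
        assert abs(abs(res.preferred_phase) - np.pi) < 0.5

    def test_uniform_phases_not_significant(self):
        r = np.random.default_rng(0)
        phases = r.uniform(-np.pi, np.pi, 1000)
        kappa, _ = vonmises_kappa_mle(phases)
        assert kappa < 0.1
        # significance requires BOTH kappa > 0.1 and p < 0.05
        assert not (kappa > 0.1 and rayleigh_p(phases) < 0.05)

    def test_kappa_threshold_gates_significance(self):
        """High n can give p < 0.05 at kappa below 0.1: still not significant."""
        r = np.random.default_rng(3)
        phases = r.vonmises(0.0, 0.09, 200_000)
        kappa, _ = vonmises_kappa_mle(phases)
        assert kappa < 0.1
        # construct the decision the way phase_locking does
        significant = kappa > 0.1 and rayleigh_p(phases[:5000]) < 0.05
        assert not significant

    def test_rayleigh_type_one_error_calibrated(self):
        r = np.random.default_rng(99)
        rejections = sum(rayleigh_p(r.uniform(-np.pi, np.pi, 80)) < 0.05 for _ in range(400))
        assert abs(rejections / 400 - 0.05) <= 0.03

    def test_too_few_spikes_rejected(self):
        tr = SpikeTrain(times=np.arange(5) + 0.5, zone="z")
        lfp = np.random.default_rng(0).standard_normal(int(10 * 1250))
        with pytest.raises(ValueError):
            phase_locking(tr, lfp, 1250.0, [(0.0, 10.0)])
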