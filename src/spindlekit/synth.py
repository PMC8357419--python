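"""Ground-truthed synthetic data: LFP/EEG, EMG, spike trains, age cohorts.

Every generator is a pure function of (spec, seed). The generators emulate
the statistical structure the analysis assumes: pink-noise background with
injected spindle-band events (8-25 Hz bursts of controlled duration,
amplitude, waveform asymmetry and spatial footprint), gamma bursts whose
amplitude envelope is shared with the spindle event, nuchal EMG with
tonic/atonic bouts and brief myoclonic twitches, spike trains with
event-modulated rate and von Mises phase preference, and multi-animal
cohorts whose per-animal feature means follow a known polynomial age
trajectory with a stored interior extremum.

Waveform asymmetry is produced by second-harmonic distortion,
``sin(phi) - a * cos(2*phi)``: the even harmonic sharpens peaks and flattens
troughs, so the extrema sharpness ratio grows monotonically with ``a`` over
the usable range a in [0, ~0.25] (beyond that the trough splits into two
minima and the mapping folds back).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ChannelInfo, Recording, SubjectInfo

__all__ = [
    "SynthEvent",
    "SynthLFPSpec",
    "SynthSpikesSpec",
    "CohortSpec",
    "pink_noise",
    "event_waveform",
    "generate_lfp",
    "generate_emg",
    "generate_spikes",
    "generate_cohort",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SynthEvent:
    """One injected spindle-band event."""

    onset: float  # s
    duration: float  # s
    freq: float = 12.0  # Hz, center frequency (8-25 typical)
    amplitude: float = 100.0  # uV, carrier peak amplitude
    asymmetry: float = 0.0  # second-harmonic skew, >= 0
    channels: tuple[int, ...] = (0,)  # spatial footprint (channel indices)


@dataclass
class SynthLFPSpec:
    n_channels: int = 1
    fs: float = 1250.0
    duration: float = 60.0
    beta: float = 1.5  # background 1/f^beta exponent
    background_rms: float = 20.0  # uV
    events: list[SynthEvent] = field(default_factory=list)
    event_rate: float | None = None  # Hz; used when events list is empty
    gamma_coupling: bool = False
    gamma_freq: float | tuple[float, ...] = 50.0
    gamma_share: float = 0.0  # envelope-sharing coefficient in [0, 1]
    gamma_amplitude_factor: float = 0.25  # gamma peak as fraction of event amp
    discontinuity: float = 0.0  # fraction of background time silenced

    def __post_init__(self) -> None:
        if not 0 <= self.gamma_share <= 1:
            raise ValueError("gamma_share must lie in [0, 1]")
        if not 0 <= self.discontinuity < 1:
            raise ValueError("discontinuity fraction must lie in [0, 1)")


@dataclass
class SynthSpikesSpec:
    baseline_rate: float = 2.0  # Hz
    event_gain: float = 3.0  # multiplicative rate factor during events
    kappa: float = 0.0  # von Mises concentration of phase-locked spikes
    preferred_phase: float = np.pi  # rad (trough of the cosine convention)
    refractory: float = 0.002  # s
    duplicate_prob: float = 0.0  # echo probability on a paired channel
    zones: dict[int, str] = field(default_factory=lambda: {0: "deep-A"})
    amplitude_factor: float = 8.0  # spike peak as multiple of high-band floor

    def __post_init__(self) -> None:
        if self.baseline_rate < 0 or self.event_gain < 0:
            raise ValueError("rates must be non-negative")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass
class CohortSpec:
    """A multi-animal cohort whose feature mean follows a polynomial of age.

    ``coeffs`` are numpy polyval coefficients (highest power first) of the
    trajectory mean as a function of age. The true interior extremum age (if
    any) is derived analytically and stored with the ground truth.
    """

    ages: tuple[float, ...] = tuple(range(5, 15))  # P5-P14 analog
    animals_per_age: int = 7
    coeffs: tuple[float, ...] = (1.0, -17.0, 80.0)  # vertex at 8.5
    noise_sd: float = 1.0
    feature: str = "feature"

    def __post_init__(self) -> None:
        if len(set(self.ages)) < 3:
            raise ValueError("cohort needs at least 3 distinct ages")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")

    def true_nadir(self) -> float | None:
        """Age of the first interior extremum of the mean trajectory."""
        der = np.polyder(np.asarray(self.coeffs, dtype=float))
        if der.size < 2:
            return None
        roots = np.roots(der)
        lo, hi = min(self.ages), max(self.ages)
        real = sorted(
            r.real for r in roots if abs(r.imag) < 1e-9 and lo < r.real < hi
        )
        return real[0] if real else None


# ---------------------------------------------------------------------------
# Building blocks
# ---------------------------------------------------------------------------

def pink_noise(n: int, fs: float, beta: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^beta noise by spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-beta / 2)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def event_waveform(
    freq: float,
    duration: float,
    fs: float,
    amplitude: float = 1.0,
    asymmetry: float = 0.0,
    taper: float = 0.2,
) -> np.ndarray:
    """Spindle-band burst: skewed carrier under a Tukey envelope."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phi = 2 * np.pi * freq * t
    carrier = np.sin(phi) - asymmetry * np.cos(2 * phi)
    return amplitude * sps.windows.tukey(n, taper) * carrier


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

def _place_events(spec: SynthLFPSpec, rng: np.random.Generator) -> list[SynthEvent]:
    events = list(spec.events)
    if not events and spec.event_rate:
        n_ev = rng.poisson(spec.event_rate * spec.duration)
        t = 1.0
        for _ in range(n_ev):
            dur = float(rng.uniform(0.5, 2.0))
            gap = float(rng.exponential(max(1 / spec.event_rate - dur, 0.5)))
            onset = t + gap
            if onset + dur > spec.duration - 1.0:
                break
            events.append(
                SynthEvent(
                    onset=onset,
                    duration=dur,
                    freq=float(rng.uniform(10, 18)),
                    amplitude=spec.background_rms * 5,
                    channels=(0,),
                )
            )
            t = onset + dur
    return events


def generate_lfp(spec: SynthLFPSpec, seed: int) -> tuple[Recording, pd.DataFrame]:
    """Synthesize a multichannel LFP recording plus its ground-truth table.

    Raises if two injected events overlap on a channel, keeping the ground
    truth unambiguous for recall/precision scoring.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.fs))
    sig = np.vstack(
        [pink_noise(n, spec.fs, spec.beta, spec.background_rms, rng) for _ in range(spec.n_channels)]
    )

    if spec.discontinuity > 0:
        # silence random 1-s background blocks (trace-alternant-like gaps)
        n_blocks = int(spec.discontinuity * spec.duration)
        starts = rng.choice(int(spec.duration) - 1, size=min(n_blocks, int(spec.duration) - 1), replace=False)
        for s in starts:
            sig[:, int(s * spec.fs) : int((s + 1) * spec.fs)] *= 0.05

    events = _place_events(spec, rng)
    per_channel: dict[int, list[tuple[float, float]]] = {}
    rows = []
    for k, ev in enumerate(events):
        if ev.onset < 0 or ev.onset + ev.duration > spec.duration:
            raise ValueError(f"event {k} extends outside the recording")
        if ev.amplitude <= 0:
            raise ValueError(f"event {k} amplitude must be positive")
        wav = event_waveform(ev.freq, ev.duration, spec.fs, ev.amplitude, ev.asymmetry)
        i0 = int(round(ev.onset * spec.fs))
        for ch in ev.channels:
            if ch >= spec.n_channels:
                raise ValueError(f"event {k} footprint channel {ch} outside recording")
            for a, b in per_channel.get(ch, []):
                if ev.onset < b and a < ev.onset + ev.duration:
                    raise ValueError(f"event {k} overlaps an earlier event on channel {ch}")
            per_channel.setdefault(ch, []).append((ev.onset, ev.onset + ev.duration))
            sig[ch, i0 : i0 + wav.size] += wav
            if spec.gamma_coupling and spec.gamma_share > 0:
                t = np.arange(wav.size) / spec.fs
                env = sps.windows.tukey(wav.size, 0.2)
                gfreqs = spec.gamma_freq if isinstance(spec.gamma_freq, tuple) else (spec.gamma_freq,)
                for gf in gfreqs:
                    sig[ch, i0 : i0 + wav.size] += (
                        spec.gamma_share
                        * spec.gamma_amplitude_factor
                        * ev.amplitude
                        * env
                        * np.sin(2 * np.pi * gf * (t + ev.onset))
                    )
            rows.append(
                {
                    "event_id": k,
                    "channel": ch,
                    "start_s": ev.onset,
                    "end_s": ev.onset + ev.duration,
                    "start_idx": i0,
                    "end_idx": i0 + wav.size,
                    "freq_hz": ev.freq,
                    "amplitude_uv": ev.amplitude,
                    "asymmetry": ev.asymmetry,
                }
            )

    truth = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "channel",
            "start_s",
            "end_s",
            "start_idx",
            "end_idx",
            "freq_hz",
            "amplitude_uv",
            "asymmetry",
        ],
    )
    chans = [ChannelInfo(label=f"ch{i}", position=(0.0, 100.0 * i)) for i in range(spec.n_channels)]
    rec = Recording(
        signal=sig,
        fs=spec.fs,
        channels=chans,
        subject=SubjectInfo(recording_id=f"synth-{seed}"),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def generate_emg(
    duration: float,
    fs: float,
    wake_bouts: list[tuple[float, float]] | None = None,
    twitch_times: list[float] | None = None,
    twitch_duration: float = 0.3,
    atonia_rms: float = 5.0,
    wake_factor: float = 6.0,
    twitch_factor: float = 8.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Synthesize a nuchal EMG trace from a bout plan.

    Atonia background is low-RMS broadband noise; wake bouts and twitches are
    high-frequency (> 300 Hz) noise bursts. Twitches must fall on the atonia
    background (a twitch inside a wake bout is a plan error) and are shorter
    than 1.5 s by construction.
    """
    wake_bouts = sorted(wake_bouts or [])
    twitch_times = sorted(twitch_times or [])
    if twitch_duration >= 1.5:
        raise ValueError("twitch duration must be < 1.5 s")
    for i in range(1, len(wake_bouts)):
        if wake_bouts[i][0] < wake_bouts[i - 1][1]:
            raise ValueError("wake bouts overlap")
    for tt in twitch_times:
        for a, b in wake_bouts:
            if a <= tt < b:
                raise ValueError(f"twitch at {tt} s lies inside wake bout [{a}, {b})")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    if fs <= 600:
        raise ValueError("EMG sampling rate must exceed 600 Hz")
    # high-frequency carrier, so the 300 Hz high-pass retains muscle tone
    carrier = rng.standard_normal(n)
    sos = sps.butter(4, 300, btype="highpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, carrier)
    carrier /= carrier.std()

    env = np.full(n, atonia_rms)
    for a, b in wake_bouts:
        env[int(a * fs) : int(b * fs)] = atonia_rms * wake_factor
    for tt in twitch_times:
        i0 = int((tt - twitch_duration / 2) * fs)
        i1 = i0 + int(twitch_duration * fs)
        env[max(i0, 0) : min(i1, n)] = atonia_rms * twitch_factor
    emg = carrier * env
    truth = {
        "wake_bouts": wake_bouts,
        "twitch_times": twitch_times,
        "twitch_duration": twitch_duration,
        "atonia_rms": atonia_rms,
    }
    return emg, truth


# ---------------------------------------------------------------------------
# Spikes
# ---------------------------------------------------------------------------

def spike_template(fs: float, width_s: float = 0.0006) -> np.ndarray:
    """Biphasic extracellular spike shape (negative-leading), ~0.6 ms wide."""
    n = max(int(round(width_s * fs)), 3)
    t = np.linspace(-1, 1, 2 * n + 1)
    return -np.exp(-(t ** 2) / 0.08) + 0.45 * np.exp(-((t - 0.55) ** 2) / 0.18)


def generate_spikes(
    spec: SynthSpikesSpec,
    lfp: Recording,
    events: pd.DataFrame,
    seed: int,
    inject: bool = True,
) -> pd.DataFrame:
    """Draw ground-truth spike times and optionally inject spike transients.

    Baseline activity is homogeneous Poisson; during ground-truth events the
    rate is multiplied by ``event_gain``. When ``kappa`` > 0, event spikes are
    placed at carrier phases drawn von Mises(preferred_phase, kappa), where
    phase follows the analytic-signal convention (0 at band-passed peak,
    +-pi at trough). Duplicate detections are emulated by echoing spikes onto
    a paired channel within 2 ms with probability ``duplicate_prob``.
    """
    rng = np.random.default_rng(seed)
    duration = lfp.duration
    channels = sorted(spec.zones)
    rows = []
    for ch in channels:
        ev = events[events["channel"] == ch] if len(events) else events
        # baseline Poisson outside events
        n_base = rng.poisson(spec.baseline_rate * duration)
        base_times = np.sort(rng.uniform(0, duration, n_base))
        in_event = np.zeros(base_times.size, dtype=bool)
        for _, r in ev.iterrows():
            in_event |= (base_times >= r["start_s"]) & (base_times < r["end_s"])
        base_times = base_times[~in_event]
        for t in base_times:
            rows.append({"time_s": t, "channel": ch, "zone": spec.zones[ch], "phase": np.nan, "in_event": False})
        # event spikes at modulated rate, phase-locked when kappa > 0
        for _, r in ev.iterrows():
            lam = spec.baseline_rate * spec.event_gain
            n_ev = rng.poisson(lam * (r["end_s"] - r["start_s"]))
            f = r.get("freq_hz", 12.0)
            for _ in range(n_ev):
                if spec.kappa > 0:
                    phase = float(rng.vonmises(spec.preferred_phase, spec.kappa))
                    # carrier sin(2 pi f t'), analytic phase = 2 pi f t' - pi/2
                    cycles = rng.integers(0, max(int((r["end_s"] - r["start_s"]) * f), 1))
                    t_local = ((phase + np.pi / 2) / (2 * np.pi) + cycles) / f
                    t = r["start_s"] + t_local
                    if t >= r["end_s"]:
                        continue
                else:
                    phase = np.nan
                    t = float(rng.uniform(r["start_s"], r["end_s"]))
                rows.append({"time_s": t, "channel": ch, "zone": spec.zones[ch], "phase": phase, "in_event": True})

    truth = pd.DataFrame(rows, columns=["time_s", "channel", "zone", "phase", "in_event"])
    truth = truth.sort_values("time_s", kind="stable").reset_index(drop=True)

    # refractory thinning per channel
    keep = np.ones(len(truth), dtype=bool)
    for ch in channels:
        idx = truth.index[truth["channel"] == ch].to_numpy()
        last = -np.inf
        for i in idx:
            t = truth.at[i, "time_s"]
            if t - last < spec.refractory:
                keep[i] = False
            else:
                last = t
    truth = truth[keep].reset_index(drop=True)

    # duplicate echoes on a paired channel in the same zone
    if spec.duplicate_prob > 0 and len(channels) >= 2:
        echoes = []
        pair = {channels[i]: channels[(i + 1) % len(channels)] for i in range(len(channels))}
        for _, r in truth.iterrows():
            if rng.uniform() < spec.duplicate_prob:
                echoes.append(
                    {
                        "time_s": r["time_s"] + float(rng.uniform(0.0002, 0.0018)),
                        "channel": pair[r["channel"]],
                        "zone": r["zone"],
                        "phase": r["phase"],
                        "in_event": r["in_event"],
                    }
                )
        if echoes:
            truth = (
                pd.concat([truth, pd.DataFrame(echoes)], ignore_index=True)
                .sort_values("time_s", kind="stable")
                .reset_index(drop=True)
            )

    if inject:
        tmpl = spike_template(lfp.fs)
        half = tmpl.size // 2
        sos = sps.butter(4, [250, min(2500, lfp.fs / 2 * 0.95)], btype="bandpass", fs=lfp.fs, output="sos")
        for ch in channels:
            hb = sps.sosfiltfilt(sos, lfp.signal[ch])
            floor = np.median(np.abs(hb)) / 0.6745
            amp = spec.amplitude_factor * floor
            for t in truth.loc[truth["channel"] == ch, "time_s"]:
                i = int(round(t * lfp.fs))
                a, b = i - half, i + half + 1
                if a >= 0 and b <= lfp.n_samples:
                    lfp.signal[ch, a:b] += amp * tmpl
    return truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, seed: int) -> tuple[pd.DataFrame, float | None]:
    """Per-animal feature table following the spec's polynomial age trend."""
    rng = np.random.default_rng(seed)
    rows = []
    aid = 0
    coeffs = np.asarray(spec.coeffs, dtype=float)
    for age in spec.ages:
        mean = float(np.polyval(coeffs, age))
        for _ in range(spec.animals_per_age):
            rows.append(
                {
                    "animal_id": f"a{aid:03d}",
                    "age": float(age),
                    "feature": spec.feature,
                    "value": mean + float(rng.normal(0, spec.noise_sd)),
                }
            )
            aid += 1
    return pd.DataFrame(rows), spec.true_nadir()
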