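"""EMG-based behavioral state scoring for neonatal rodents.

The nuchal/ventral EMG is high-pass filtered at 300 Hz, rectified and
smoothed (moving RMS, 100 ms default) to obtain a power envelope. A tone
threshold is set at ``mean + multiplier * SD`` of the envelope, with the
multiplier constrained to the 1.5-3.5 range used for per-recording tuning.
Supra-threshold runs lasting at least 1.5 s are wake; shorter supra-threshold
bursts on an atonia background are myoclonic twitches; sub-threshold runs of
at least 2 s are muscle atonia. Atonia blocks of at least 10 s with no twitch
are scored quiet sleep; atonia blocks containing twitches are active sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["EMGEnvelope", "StateSegments", "emg_envelope", "score_states", "twitch_times"]

MIN_WAKE_S = 1.5
MIN_ATONIA_S = 2.0
MIN_QUIET_SLEEP_S = 10.0


@dataclass
class EMGEnvelope:
    envelope: np.ndarray  # rectified, smoothed high-passed EMG, uV
    fs_env: float
    mean_power: float
    threshold: float
    sd_multiplier: float
    degenerate: bool = False  # flat/zero input: threshold uninformative


@dataclass
class StateSegments:
    """Labeled half-open intervals [start_s, end_s).

    ``intervals`` holds (start, end, label) with labels in
    {wake, twitch, atonia, quiet_sleep, active_sleep}. quiet_sleep and
    active_sleep intervals overlay atonia blocks; wake/atonia/twitch runs do
    not overlap each other.
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)
    threshold: float = 0.0
    sd_multiplier: float = 0.0

    def by_label(self, label: str) -> list[tuple[float, float]]:
        return [(a, b) for a, b, l in self.intervals if l == label]


def emg_envelope(
    emg: np.ndarray,
    fs: float,
    smooth_win: float = 0.1,
    sd_multiplier: float = 2.5,
    fs_env: float = 200.0,
    allow_out_of_range: bool = False,
) -> EMGEnvelope:
    """Compute the EMG power envelope and tone threshold.

    ``sd_multiplier`` must lie in [1.5, 3.5] unless ``allow_out_of_range``;
    the default 2.5 is the midpoint of that per-recording tuning range.
    """
    if fs <= 600:
        raise ValueError("EMG sampling rate must exceed 600 Hz for the 300 Hz high-pass")
    if not (1.5 <= sd_multiplier <= 3.5) and not allow_out_of_range:
        raise ValueError("sd_multiplier outside the 1.5-3.5 range (set allow_out_of_range to force)")
    emg = np.asarray(emg, dtype=float)
    if emg.size == 0:
        raise ValueError("empty EMG signal")

    degenerate = np.ptp(emg) == 0
    if degenerate:
        hp = np.zeros_like(emg)
    else:
        sos = sps.butter(4, 300, btype="highpass", fs=fs, output="sos")
        hp = sps.sosfiltfilt(sos, emg)
    # moving RMS
    win = max(int(round(smooth_win * fs)), 1)
    kernel = np.ones(win) / win
    env = np.sqrt(np.convolve(hp ** 2, kernel, mode="same"))
    # decimate envelope to fs_env for compact downstream interval logic
    step = max(int(round(fs / fs_env)), 1)
    env = env[::step]
    fs_out = fs / step
    # threshold statistics from the instantaneous rectified high-passed
    # signal (the "power" the tone rule refers to), not the smoothed
    # envelope: the raw amplitude distribution is wide, which places the
    # threshold above the envelope's quiescent fluctuations and keeps pure
    # atonia noise from generating phantom twitches
    rect = np.abs(hp)
    mean_power = float(rect.mean())
    sd = float(rect.std())
    threshold = mean_power + sd_multiplier * sd
    return EMGEnvelope(
        envelope=env,
        fs_env=fs_out,
        mean_power=mean_power,
        threshold=threshold,
        sd_multiplier=sd_multiplier,
        degenerate=degenerate or sd == 0,
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of constant boolean value as (start, end, value)."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        j = i
        while j < n and mask[j] == mask[i]:
            j += 1
        out.append((i, j, bool(mask[i])))
        i = j
    return out


def score_states(env: EMGEnvelope) -> StateSegments:
    """Score wake / twitch / atonia / quiet-sleep / active-sleep intervals."""
    if env.envelope.size == 0:
        raise ValueError("empty envelope")
    fs = env.fs_env
    supra = env.envelope > env.threshold
    runs = _runs(supra)

    # first pass: classify runs by duration rules
    labels: list[str | None] = []
    for i0, i1, high in runs:
        dur = (i1 - i0) / fs
        if high:
            labels.append("wake" if dur >= MIN_WAKE_S else "twitch?")
        else:
            labels.append("atonia" if dur >= MIN_ATONIA_S else None)

    # twitches require an atonia background; merge short unlabeled gaps into
    # agreeing flanks, else leave unlabeled
    for k, lab in enumerate(labels):
        if lab == "twitch?":
            prev_ok = k == 0 or labels[k - 1] == "atonia"
            next_ok = k == len(labels) - 1 or labels[k + 1] == "atonia"
            labels[k] = "twitch" if (prev_ok and next_ok) else None
        elif lab is None:
            prev = labels[k - 1] if k > 0 else None
            nxt = labels[k + 1] if k < len(labels) - 1 else None
            if prev == "atonia" and nxt == "atonia":
                labels[k] = "atonia"

    intervals: list[tuple[float, float, str]] = []
    for (i0, i1, _), lab in zip(runs, labels):
        if lab in ("wake", "atonia", "twitch"):
            intervals.append((i0 / fs, i1 / fs, lab))

    # atonia blocks: contiguous atonia runs with contained twitches
    block_start = None
    block_end = None
    block_twitches = 0
    blocks: list[tuple[float, float, int]] = []

    def close_block():
        nonlocal block_start, block_end, block_twitches
        if block_start is not None:
            blocks.append((block_start, block_end, block_twitches))
        block_start = block_end = None
        block_twitches = 0

    for (i0, i1, _), lab in zip(runs, labels):
        t0, t1 = i0 / fs, i1 / fs
        if lab == "atonia":
            if block_start is None:
                block_start = t0
            block_end = t1
        elif lab == "twitch" and block_start is not None:
            block_twitches += 1
            block_end = t1
        else:
            close_block()
    close_block()

    for a, b, ntw in blocks:
        if ntw > 0:
            intervals.append((a, b, "active_sleep"))
        elif b - a >= MIN_QUIET_SLEEP_S:
            intervals.append((a, b, "quiet_sleep"))

    intervals.sort()
    return StateSegments(intervals=intervals, threshold=env.threshold, sd_multiplier=env.sd_multiplier)


def twitch_times(segments: StateSegments) -> np.ndarray:
    """Twitch timestamps: midpoint of each supra-threshold twitch run."""
    return np.array([(a + b) / 2 for a, b in segments.by_label("twitch")])
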