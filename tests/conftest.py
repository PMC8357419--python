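import numpy as np
import pytest
from scipy import signal as sps

from spindlekit.synth import SynthEvent, SynthLFPSpec, generate_lfp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_event_recording(
    n_events: int,
    seed: int,
    fs: float = 1250.0,
    amplitude: float = 100.0,
    background_rms: float = 20.0,
    gap: tuple[float, float] = (2.0, 3.0),
    dur: tuple[float, float] = (0.3, 2.0),
    freq: tuple[float, float] = (10.0, 18.0),
    asymmetry: float = 0.0,
    **spec_kwargs,
):
    """Recording with ``n_events`` injected spindle-band events and its truth."""
    rg = np.random.default_rng(seed)
    events = []
    t = 2.0
    for _ in range(n_events):
        d = float(rg.uniform(*dur))
        events.append(
            SynthEvent(
                onset=t,
                duration=d,
                freq=float(rg.uniform(*freq)),
                amplitude=amplitude,
                asymmetry=asymmetry,
            )
        )
        t += d + float(rg.uniform(*gap))
    spec = SynthLFPSpec(
        n_channels=1,
        fs=fs,
        duration=t + 2.0,
        background_rms=background_rms,
        events=events,
        **spec_kwargs,
    )
    return generate_lfp(spec, seed=seed + 1)


def match_events(truth, detected, min_frac: float = 0.5):
    """Greedy truth-to-detection matching by interval overlap.

    Returns (n_matched, boundary_errors) where each boundary error is the
    larger of the start and end discrepancies of a matched pair.
    """
    used = set()
    errors = []
    matched = 0
    for _, row in truth.iterrows():
        for i, ev in enumerate(detected):
            if i in used:
                continue
            ov = min(row.end_s, ev.end_s) - max(row.start_s, ev.start_s)
            if ov > min_frac * (row.end_s - row.start_s):
                used.add(i)
                matched += 1
                errors.append(max(abs(ev.start_s - row.start_s), abs(ev.end_s - row.end_s)))
                break
    return matched, np.array(errors)


def tukey_burst(freq: float, duration: float, fs: float, amplitude: float, taper: float = 0.1):
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    return amplitude * sps.windows.tukey(n, taper) * np.sin(2 * np.pi * freq * t)
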