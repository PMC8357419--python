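"""Detect and characterize spindle-band oscillations in a synthetic LFP.

Builds a one-channel neonatal-style recording with 15 injected spindle-band
events on a pink-noise background, runs the PAR detector, and characterizes
each detection (Hilbert power, waveform asymmetry).
"""

import numpy as np

from spindlekit import compute_par, detect_spindle_events, event_power, waveform_asymmetry
from spindlekit.synth import SynthEvent, SynthLFPSpec, generate_lfp

rng = np.random.default_rng(0)
events = []
t = 2.0
for _ in range(15):
    dur = float(rng.uniform(0.5, 2.0))
    events.append(SynthEvent(onset=t, duration=dur, freq=float(rng.uniform(10, 18)),
                             amplitude=100.0, asymmetry=0.15))
    t += dur + float(rng.uniform(2.0, 3.0))
spec = SynthLFPSpec(fs=1250.0, duration=t + 2.0, background_rms=20.0, events=events)
rec, truth = generate_lfp(spec, seed=1)

par, powers = compute_par(rec.signal[0], rec.fs)
detected = detect_spindle_events(par, powers, sleep_mask=[(0.0, rec.duration)])

print(f"injected {len(truth)} events, detected {len(detected)}")
print(f"{'start_s':>8} {'dur_s':>6} {'peak_par':>8} {'power_uV':>9} {'ESR':>6}")
for ev in detected[:10]:
    p = event_power(ev.start_s, ev.end_s, rec.signal[0], rec.fs)
    esr = waveform_asymmetry(ev.start_s, ev.end_s, rec.signal[0], rec.fs).esr
    print(f"{ev.start_s:8.2f} {ev.duration:6.2f} {ev.peak_par:8.2f} {p:9.1f} {esr:6.2f}")

# peak_par near 1 means spindle-band power dominates both flanking bands;
# power ~ the injected 100 uV carrier (median Hilbert envelope over the
# event); ESR > 1 reflects the injected peak-sharpening asymmetry (0.15).
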