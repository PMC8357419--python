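"""Score wake / twitch / atonia / sleep states from a synthetic EMG.

Builds a 2-minute nuchal EMG with two wake bouts and two myoclonic twitches,
computes the tone envelope and threshold, and prints the scored intervals.
"""

from spindlekit import emg_envelope, score_states, twitch_times
from spindlekit.synth import generate_emg

emg, plan = generate_emg(
    duration=120.0,
    fs=5000.0,
    wake_bouts=[(20.0, 24.0), (70.0, 74.0)],
    twitch_times=[40.0, 50.0],
    seed=0,
)
env = emg_envelope(emg, 5000.0)
segs = score_states(env)

print(f"tone threshold: {env.threshold:.1f} uV (mean + {env.sd_multiplier} SD)")
for a, b, label in segs.intervals:
    print(f"  {a:7.2f} - {b:7.2f}  {label}")
print("twitch centers:", [round(t, 2) for t in twitch_times(segs)])

# Wake = sustained supra-threshold tone >= 1.5 s; twitches are brief bursts
# on an atonia background; twitch-free atonia blocks >= 10 s are quiet sleep,
# twitch-containing blocks active sleep. Recovered twitch centers should sit
# within ~0.1 s of the planned times (40 s, 50 s).
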