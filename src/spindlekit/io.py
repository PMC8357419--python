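"""Readers and writers for the raw formats the pipeline touches.

Multichannel extracellular recordings arrive as interleaved signed 16-bit
binary (frame-major: sample 0 of every channel, then sample 1, ...) with a
JSON channel-map sidecar carrying labels, geometry and the acquisition gain.
Clinical scalp EEG arrives as EDF/EDF+ with 10-20 labels and is read through
MNE. All amplitudes are microvolts after gain application; time is seconds,
intervals half-open [start, end), sample indices 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps


@dataclass
class ChannelInfo:
    """Per-channel metadata.

    position is a 2-D (x, y) coordinate in micrometres for surface arrays or
    (0, depth) for linear probes; zone tags the cortical layer grouping used
    by the spiking analysis.
    """

    label: str
    position: tuple[float, float] = (0.0, 0.0)
    zone: str = "none"  # superficial | deep | none (or deep-A / deep-B)
    functional: bool = True


@dataclass
class SubjectInfo:
    species: str = "mouse"  # mouse | human
    age: float = 0.0
    age_unit: str = "postnatal_days"  # postnatal_days | post_gestational_weeks
    recording_id: str = "rec"


@dataclass
class Recording:
    """A multichannel recording: channels x samples matrix in microvolts."""

    signal: np.ndarray
    fs: float
    channels: list[ChannelInfo] = field(default_factory=list)
    subject: SubjectInfo = field(default_factory=SubjectInfo)

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            self.channels = [ChannelInfo(label=f"ch{i}") for i in range(self.n_channels)]
        if len(self.channels) != self.n_channels:
            raise ValueError("channel metadata length does not match signal rows")
        if not any(c.functional for c in self.channels):
            raise ValueError("at least one channel must be functional")
        for c in self.channels:
            if not np.all(np.isfinite(c.position)):
                raise ValueError(f"non-finite position on channel {c.label}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel_index(self, label: str) -> int:
        for i, c in enumerate(self.channels):
            if c.label == label:
                return i
        raise KeyError(f"unknown channel label {label!r}")


# ---------------------------------------------------------------------------
# Interleaved int16 binary + JSON sidecar
# ---------------------------------------------------------------------------

def write_binary_int16(path: str | Path, rec: Recording, gain_uv_per_bit: float = 1.0) -> None:
    """Write a recording as frame-major interleaved int16 plus a JSON sidecar.

    Values are quantized as round(signal / gain). Out-of-range values raise
    rather than wrap.
    """
    path = Path(path)
    q = np.round(rec.signal / gain_uv_per_bit)
    if np.any(np.abs(q) > 32767):
        raise ValueError("signal exceeds int16 range at this gain")
    data = q.astype("<i2").T  # samples x channels -> frame-major on ravel
    path.write_bytes(data.tobytes())
    sidecar = {
        "channels": [
            {
                "label": c.label,
                "position_um": list(c.position),
                "zone": c.zone,
                "functional": c.functional,
            }
            for c in rec.channels
        ],
        "fs": rec.fs,
        "gain_uv_per_bit": gain_uv_per_bit,
        "subject": {
            "species": rec.subject.species,
            "age": rec.subject.age,
            "age_unit": rec.subject.age_unit,
            "recording_id": rec.subject.recording_id,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_binary_int16(
    path: str | Path,
    channel_map: str | Path | dict | None = None,
    fs: float | None = None,
) -> Recording:
    """Read frame-major interleaved int16 binary into a Recording.

    The sidecar (``<path>.json`` by default) must provide the channel list and
    the gain in microvolts per bit; the acquisition gain is hardware-specific
    and therefore required rather than defaulted.
    """
    path = Path(path)
    if channel_map is None:
        channel_map = path.with_suffix(path.suffix + ".json")
    if not isinstance(channel_map, dict):
        channel_map = json.loads(Path(channel_map).read_text())
    chans = [
        ChannelInfo(
            label=c["label"],
            position=tuple(c.get("position_um", (0.0, 0.0))),
            zone=c.get("zone", "none"),
            functional=c.get("functional", True),
        )
        for c in channel_map["channels"]
    ]
    n_ch = len(chans)
    if n_ch == 0:
        raise ValueError("channel map lists no channels")
    gain = float(channel_map["gain_uv_per_bit"])
    fs = float(fs if fs is not None else channel_map["fs"])
    raw = path.read_bytes()
    frame_bytes = 2 * n_ch
    if len(raw) % frame_bytes != 0:
        raise ValueError(
            f"truncated file: {len(raw)} bytes is not a whole number of "
            f"{n_ch}-channel frames ({len(raw) / frame_bytes:.2f} frames)"
        )
    data = np.frombuffer(raw, dtype="<i2").reshape(-1, n_ch).T.astype(float) * gain
    subj = channel_map.get("subject", {})
    subject = SubjectInfo(
        species=subj.get("species", "mouse"),
        age=subj.get("age", 0.0),
        age_unit=subj.get("age_unit", "postnatal_days"),
        recording_id=subj.get("recording_id", path.stem),
    )
    return Recording(signal=data, fs=fs, channels=chans, subject=subject)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

# Channel preference for scalp analyses: parietal electrodes over primary
# somatosensory cortex first, central electrodes as fallback.
EDF_PREFERRED = ("P3", "P4")
EDF_FALLBACK = ("C3", "C4")


def read_edf(path: str | Path, channel_selectors: list[str] | None = None) -> Recording:
    """Read an EDF/EDF+ file, selecting parietal (P3/P4) then central (C3/C4).

    If ``channel_selectors`` is given those labels are used verbatim instead
    of the preference order. The returned recording carries a
    ``fallback_used`` attribute flagging selection of central electrodes.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)

    def match(label: str) -> str | None:
        for name in available:
            if name == label or name.upper().startswith(label.upper()):
                return name
        return None

    fallback_used = False
    if channel_selectors:
        picks = [match(lbl) for lbl in channel_selectors]
        picks = [p for p in picks if p is not None]
        if not picks:
            raise ValueError(f"none of {channel_selectors} present; available: {available}")
    else:
        picks = [m for lbl in EDF_PREFERRED if (m := match(lbl))]
        if not picks:
            picks = [m for lbl in EDF_FALLBACK if (m := match(lbl))]
            fallback_used = bool(picks)
        if not picks:
            raise ValueError(
                f"no parietal (P3/P4) or central (C3/C4) channel found; available: {available}"
            )
        picks = picks[:1]  # a single channel is analyzed per subject
    data = raw.get_data(picks=picks) * 1e6  # MNE returns volts
    chans = [ChannelInfo(label=p) for p in picks]
    rec = Recording(
        signal=data,
        fs=float(raw.info["sfreq"]),
        channels=chans,
        subject=SubjectInfo(species="human", recording_id=Path(path).stem),
    )
    rec.fallback_used = fallback_used
    return rec


def write_edf(path: str | Path, rec: Recording) -> None:
    """Write a minimal single-record-per-second EDF file (16-bit).

    Covers the subset of EDF needed to round-trip synthetic test signals:
    continuous signals, one data-record per second, physical range set from
    the data. Truncates to a whole number of seconds.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // fs
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    ns = rec.n_channels
    x = rec.signal[:, : n_rec * fs]
    pmax = max(1.0, float(np.max(np.abs(x)) * 1.01))
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (2 * pmax)
    dig = np.clip(np.round((x + pmax) * scale) + dmin, dmin, dmax).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s[:n].ljust(n).encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad(rec.subject.recording_id, 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + ns * 256), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    labels = b"".join(pad(c.label, 16) for c in rec.channels)
    transducer = b"".join(pad("", 80) for _ in range(ns))
    dim = b"".join(pad("uV", 8) for _ in range(ns))
    phys_min = b"".join(pad(f"{-pmax:.2f}", 8) for _ in range(ns))
    phys_max = b"".join(pad(f"{pmax:.2f}", 8) for _ in range(ns))
    dig_min = b"".join(pad(str(dmin), 8) for _ in range(ns))
    dig_max = b"".join(pad(str(dmax), 8) for _ in range(ns))
    prefilter = b"".join(pad("", 80) for _ in range(ns))
    nsamp = b"".join(pad(str(fs), 8) for _ in range(ns))
    reserved = b"".join(pad("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + dim + phys_min + phys_max)
        fh.write(dig_min + dig_max + prefilter + nsamp + reserved)
        for r in range(n_rec):
            for ch in range(ns):
                fh.write(dig[ch, r * fs : (r + 1) * fs].tobytes())


# ---------------------------------------------------------------------------
# Notch
# ---------------------------------------------------------------------------

def apply_notch(rec: Recording, freq: float, quality: float = 30.0) -> Recording:
    """Zero-phase notch filter (line-noise removal) at ``freq`` Hz."""
    if freq >= rec.fs / 2:
        raise ValueError(f"notch frequency {freq} Hz is at or above Nyquist ({rec.fs / 2} Hz)")
    b, a = sps.iirnotch(freq, quality, fs=rec.fs)
    # two cascaded passes of filtfilt deepen the stopband well past 20 dB
    filtered = sps.filtfilt(b, a, sps.filtfilt(b, a, rec.signal, axis=1), axis=1)
    out = Recording(signal=filtered, fs=rec.fs, channels=rec.channels, subject=rec.subject)
    return out
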