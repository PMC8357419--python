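"""Spindle-band oscillation detection and characterization.

Detection uses the power-asymmetry ratio (PAR) of wavelet band powers,

    PAR = (Pspi - (Plow + Phigh)) / (Pspi + Plow + Phigh)

with Pspi the 8-25 Hz spindle-band power, Plow 1-5 Hz (2-6 Hz for human
subjects younger than 40 post-gestational weeks, where delta brushes ride
slower waves) and Phigh 30-80 Hz. Candidate intervals require spindle-band
power above a MAD-scaled threshold derived within sleep; events are runs
where PAR stays above -0.1 for 0.3-5 s with a positive PAR peak.

Characterization: power = median of the rectified 8-25 Hz Hilbert envelope
over the event; spatial extent = fraction of functional channels expressing
a co-occurring event (interval intersection > 300 ms, midpoint separation
<= 50 ms); waveform asymmetry = extrema mean sharpness ratio (ESR), the mean
peak sharpness over the mean trough sharpness read from the raw trace at
+-8 ms around extrema bracketed by zero-crossings of the 5-30 Hz signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .spectral import gabor_spectrogram, whiten_ar1

__all__ = [
    "BandPowerSet",
    "PARSeries",
    "SpindleEvent",
    "AsymmetryResult",
    "band_edges",
    "compute_par",
    "detect_spindle_events",
    "event_power",
    "spatial_extent",
    "waveform_asymmetry",
]

SPINDLE_BAND = (8.0, 25.0)
LOW_BAND_RODENT = (1.0, 5.0)
LOW_BAND_HUMAN_PRETERM = (2.0, 6.0)  # subjects < 40 post-gestational weeks
HIGH_BAND = (30.0, 80.0)
PAR_CROSSING = -0.1
MIN_EVENT_S = 0.3
MAX_EVENT_S = 5.0


@dataclass
class BandPowerSet:
    pspi: np.ndarray  # spindle-band wavelet power
    plow: np.ndarray
    phigh: np.ndarray
    fs: float
    low_band: tuple[float, float] = LOW_BAND_RODENT


@dataclass
class PARSeries:
    par: np.ndarray  # in [-1, 1] wherever the denominator is positive
    fs: float
    valid: np.ndarray | None = None  # False where the denominator vanished


@dataclass
class SpindleEvent:
    channel: int
    start_s: float
    end_s: float
    peak_par: float
    power: float = np.nan  # uV, median Hilbert envelope (filled later)
    esr: float = np.nan
    extent: float = np.nan

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint(self) -> float:
        return (self.start_s + self.end_s) / 2


@dataclass
class AsymmetryResult:
    sharp_peak: float  # uV
    sharp_trough: float  # uV
    esr: float
    n_peaks: int
    n_troughs: int


def band_edges(species: str = "mouse", age_weeks: float | None = None) -> tuple[tuple[float, float], ...]:
    """(spindle, low, high) band edges for the species/age variant."""
    low = LOW_BAND_RODENT
    if species == "human" and age_weeks is not None and age_weeks < 40:
        low = LOW_BAND_HUMAN_PRETERM
    return SPINDLE_BAND, low, HIGH_BAND


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float], n_freqs: int, n_cycles: float) -> np.ndarray:
    freqs = np.geomspace(band[0], min(band[1], 0.45 * fs), n_freqs)
    ws = gabor_spectrogram(x, fs, freqs, n_cycles=n_cycles)
    return (ws.magnitude ** 2).mean(axis=0)


def compute_par(
    lfp: np.ndarray,
    fs: float,
    species: str = "mouse",
    age_weeks: float | None = None,
    n_cycles: float = 5.0,
    whiten: bool = True,
) -> tuple[PARSeries, BandPowerSet]:
    """Pointwise PAR and the wavelet band powers it is computed from."""
    if fs < 200:
        raise ValueError("sampling rate must be at least 200 Hz")
    x = np.asarray(lfp, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("flat signal: PAR undefined")
    if whiten:
        x, _ = whiten_ar1(x)
    spi_band, low_band, high_band = band_edges(species, age_weeks)
    pspi = _band_power(x, fs, spi_band, 6, n_cycles)
    plow = _band_power(x, fs, low_band, 3, n_cycles)
    phigh = _band_power(x, fs, high_band, 6, n_cycles)
    denom = pspi + plow + phigh
    valid = denom > 0
    par = np.zeros_like(denom)
    par[valid] = (pspi[valid] - (plow[valid] + phigh[valid])) / denom[valid]
    return (
        PARSeries(par=par, fs=fs, valid=valid),
        BandPowerSet(pspi=pspi, plow=plow, phigh=phigh, fs=fs, low_band=low_band),
    )


def _mask_to_bool(sleep_mask: list[tuple[float, float]], n: int, fs: float) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    for a, b in sleep_mask:
        m[int(round(a * fs)) : int(round(b * fs))] = True
    return m


def detect_spindle_events(
    par: PARSeries,
    powers: BandPowerSet,
    sleep_mask: list[tuple[float, float]],
    channel: int = 0,
    mad_multiplier: float = 3.0,
) -> list[SpindleEvent]:
    """Detect spindle-band events within the sleep mask.

    The spindle-power threshold is median + ``mad_multiplier`` x
    (median(|Pspi|)/0.6745), computed from sleep intervals only. Candidate
    runs are maximal stretches with PAR > -0.1 inside sleep; a run becomes an
    event when it lasts 0.3-5 s, its PAR peak is positive, and its
    spindle-band power reaches the threshold. Event boundaries are the full
    PAR > -0.1 run.
    """
    if not sleep_mask:
        raise ValueError("empty sleep mask")
    n = par.par.size
    fs = par.fs
    in_sleep = _mask_to_bool(sleep_mask, n, fs)
    if not in_sleep.any():
        raise ValueError("sleep mask does not intersect the record")
    pspi_sleep = powers.pspi[in_sleep]
    med = float(np.median(pspi_sleep))
    mad_scaled = float(np.median(np.abs(pspi_sleep))) / 0.6745
    threshold = med + mad_multiplier * mad_scaled

    above = (par.par > PAR_CROSSING) & in_sleep
    if par.valid is not None:
        above &= par.valid
    idx = np.flatnonzero(above)
    events: list[SpindleEvent] = []
    if idx.size == 0:
        return events
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]] + 1
    for a, b in zip(starts, ends):
        dur = (b - a) / fs
        if dur < MIN_EVENT_S or dur > MAX_EVENT_S:
            continue
        peak = float(par.par[a:b].max())
        if peak <= 0:
            continue
        if float(powers.pspi[a:b].max()) < threshold:
            continue
        events.append(SpindleEvent(channel=channel, start_s=a / fs, end_s=b / fs, peak_par=peak))
    return events


def _padded_segment(lfp: np.ndarray, fs: float, start_s: float, end_s: float, pad_s: float = 1.0):
    """Extract [start, end) with context padding for filter transients."""
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    p = int(round(pad_s * fs))
    a, b = max(i0 - p, 0), min(i1 + p, lfp.size)
    seg = np.asarray(lfp[a:b], dtype=float)
    return seg, i0 - a, i1 - a


def event_power(
    start_s: float,
    end_s: float,
    lfp: np.ndarray,
    fs: float,
    band: tuple[float, float] = SPINDLE_BAND,
) -> float:
    """Median of the spindle-band Hilbert envelope over the event (uV)."""
    if end_s <= start_s or end_s * fs > len(lfp) + 1:
        raise ValueError("interval outside the record")
    seg, j0, j1 = _padded_segment(lfp, fs, start_s, end_s)
    if seg.size < int(fs * 0.25):
        raise ValueError("interval shorter than the filter transient")
    sos = sps.butter(4, [band[0], min(band[1], 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, seg)
    env = np.abs(sps.hilbert(filt))
    return float(np.median(env[j0:j1]))


def spatial_extent(
    ref_event: SpindleEvent,
    events_by_channel: dict[int, list[SpindleEvent]],
    n_functional: int,
    min_overlap: float = 0.3,
    max_midpoint_sep: float = 0.05,
) -> float:
    """Fraction of functional channels with an event co-occurring with the
    reference event (overlap > 300 ms and midpoint separation <= 50 ms)."""
    if n_functional < 1:
        raise ValueError("need at least one functional channel")
    count = 1  # the reference channel expresses the event by definition
    for ch, evs in events_by_channel.items():
        if ch == ref_event.channel:
            continue
        for ev in evs:
            overlap = min(ref_event.end_s, ev.end_s) - max(ref_event.start_s, ev.start_s)
            if overlap > min_overlap and abs(ev.midpoint - ref_event.midpoint) <= max_midpoint_sep:
                count += 1
                break
    return count / n_functional


def waveform_asymmetry(
    start_s: float,
    end_s: float,
    lfp: np.ndarray,
    fs: float,
    offset_s: float = 0.008,
    broad_band: tuple[float, float] = (5.0, 30.0),
) -> AsymmetryResult:
    """Extrema mean sharpness ratio of an event's raw waveform.

    Zero-crossings of the broadly band-passed (5-30 Hz) signal bracket
    extrema; peaks are raw-data maxima between a rising and the next falling
    crossing, troughs raw-data minima between a falling and the next rising
    crossing. Sharpness reads the raw voltage ``offset_s`` (8 ms) before and
    after each extremum:

        sharp_peak  = mean over peaks of  (2*Vpeak - Vbefore - Vafter) / 2
        sharp_trough= mean over troughs of (Vbefore + Vafter - 2*Vtrough) / 2

    ESR = sharp_peak / sharp_trough; deviation from 1 means asymmetry.
    """
    seg, j0, j1 = _padded_segment(lfp, fs, start_s, end_s)
    sos = sps.butter(4, [broad_band[0], min(broad_band[1], 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, seg)
    off = int(round(offset_s * fs))

    neg = np.signbit(filt)
    rising = np.flatnonzero(neg[:-1] & ~neg[1:]) + 1
    falling = np.flatnonzero(~neg[:-1] & neg[1:]) + 1
    if rising.size == 0 or falling.size == 0:
        raise ValueError("no zero-crossings in the broadband-filtered event")

    def extrema(starts: np.ndarray, ends: np.ndarray, fn) -> list[int]:
        out = []
        for s in starts:
            nxt = ends[ends > s]
            if nxt.size == 0:
                break
            e = nxt[0]
            k = s + fn(seg[s:e])
            if j0 <= k < j1 and k - off >= 0 and k + off < seg.size:
                out.append(int(k))
        return out

    peaks = extrema(rising, falling, np.argmax)
    troughs = extrema(falling, rising, np.argmin)
    if not peaks or not troughs:
        raise ValueError("event contains no complete cycle")
    sharp_peak = float(np.mean([(2 * seg[k] - seg[k - off] - seg[k + off]) / 2 for k in peaks]))
    sharp_trough = float(np.mean([(seg[k - off] + seg[k + off] - 2 * seg[k]) / 2 for k in troughs]))
    esr = sharp_peak / sharp_trough if sharp_trough != 0 else np.inf
    return AsymmetryResult(
        sharp_peak=sharp_peak,
        sharp_trough=sharp_trough,
        esr=esr,
        n_peaks=len(peaks),
        n_troughs=len(troughs),
    )
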