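"""Whitening, Gabor wavelet spectrograms, oscillatory-epoch continuity,
twitch-triggered spectral averages, twitch/event cross-correlation and a
simplified aperiodic (1/f) exponent fit.

The wavelet transform uses analytic Gabor (complex Morlet) kernels with a
5-cycle Gaussian envelope by default, amplitude-calibrated so a unit-amplitude
sinusoid at a grid frequency produces magnitude ~1. Spectrograms are usually
computed on AR(1)-whitened signals to flatten the steep 1/f background of
developing cortex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
import statsmodels.api as sm

__all__ = [
    "WaveletSpectrogram",
    "OscillatoryEpochs",
    "AperiodicFit",
    "whiten_ar1",
    "gabor_kernel",
    "gabor_spectrogram",
    "spectrogram_band_power",
    "detect_oscillatory_epochs",
    "twitch_triggered_spectrogram",
    "twitch_event_xcorr",
    "aperiodic_exponent",
    "default_freq_grid",
]


def default_freq_grid(fmin: float = 1.0, fmax: float = 100.0, n: int = 53) -> np.ndarray:
    return np.geomspace(fmin, fmax, n)


@dataclass
class WaveletSpectrogram:
    magnitude: np.ndarray  # freqs x times, amplitude-calibrated
    freqs: np.ndarray  # Hz, strictly increasing
    times: np.ndarray  # s
    fs: float
    n_cycles: float = 5.0
    whitened: bool = False
    enbw: np.ndarray | None = None  # equivalent noise bandwidth per row, Hz


@dataclass
class OscillatoryEpochs:
    intervals: list[tuple[float, float]]
    threshold: float  # uV, 99th percentile of the noise-floor amplitude
    mean_duration: float  # s
    total_duration: float  # s
    wideband_power: float  # uV^2, mean x^2 within epochs


@dataclass
class AperiodicFit:
    exponent: float
    offset: float
    band: tuple[float, float]
    r_squared: float
    masked: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))


# ---------------------------------------------------------------------------
# Whitening
# ---------------------------------------------------------------------------

def whiten_ar1(x: np.ndarray) -> tuple[np.ndarray, float]:
    """First-order autoregressive whitening: ``y[t] = x[t] - phi * x[t-1]``.

    ``phi`` is the lag-1 autocorrelation estimated from the signal itself.
    The first sample is kept as-is. Returns (whitened signal, phi).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("constant input: AR(1) coefficient undefined")
    phi = float(xc[1:] @ xc[:-1]) / denom
    y = x.copy()
    y[1:] = x[1:] - phi * x[:-1]
    return y, phi


# ---------------------------------------------------------------------------
# Gabor wavelet transform
# ---------------------------------------------------------------------------

def gabor_kernel(freq: float, fs: float, n_cycles: float = 5.0) -> np.ndarray:
    """Analytic Gabor kernel, unit-gain for a sinusoid at ``freq``."""
    sigma_t = n_cycles / (2 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    env = np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    kern = env * np.exp(2j * np.pi * freq * t)
    # normalize so that conv with cos(2 pi f t) has magnitude ~1
    return kern * (2.0 / env.sum())


def gabor_spectrogram(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    n_cycles: float = 5.0,
    whiten: bool = False,
) -> WaveletSpectrogram:
    """Time-frequency magnitude via analytic Gabor wavelets."""
    x = np.asarray(x, dtype=float)
    if freqs is None:
        freqs = default_freq_grid(fmax=min(100.0, 0.45 * fs))
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if freqs.max() >= fs / 2:
        raise ValueError("max frequency at or above Nyquist")
    if whiten:
        x, _ = whiten_ar1(x)
    mags = np.empty((freqs.size, x.size))
    enbw = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        kern = gabor_kernel(f, fs, n_cycles)
        env = np.abs(kern)
        enbw[i] = fs * float(env @ env) / float(env.sum()) ** 2
        mags[i] = np.abs(sps.fftconvolve(x, kern, mode="same"))
    return WaveletSpectrogram(
        magnitude=mags,
        freqs=freqs,
        times=np.arange(x.size) / fs,
        fs=fs,
        n_cycles=n_cycles,
        whitened=whiten,
        enbw=enbw,
    )


def spectrogram_band_power(ws: WaveletSpectrogram, band: tuple[float, float]) -> float:
    """Signal power (uV^2) in ``band`` integrated from wavelet magnitudes.

    Converts amplitude-calibrated magnitude to a one-sided PSD estimate
    (mag^2 / (2 * ENBW)) and integrates over the grid, so for stationary
    noise the result approximates the band variance.
    """
    sel = (ws.freqs >= band[0]) & (ws.freqs <= band[1])
    if sel.sum() < 2:
        raise ValueError("band covers fewer than 2 grid frequencies")
    psd = (ws.magnitude[sel] ** 2).mean(axis=1) / (2 * ws.enbw[sel])
    return float(np.trapezoid(psd, ws.freqs[sel]))


# ---------------------------------------------------------------------------
# Oscillatory epochs (continuity)
# ---------------------------------------------------------------------------

def detect_oscillatory_epochs(
    x: np.ndarray,
    fs: float,
    smooth_win: float = 0.1,
    floor_window: float = 1.0,
    floor_decile: float = 0.1,
    min_duration: float = 0.1,
    merge_gap: float = 0.1,
) -> OscillatoryEpochs:
    """Epochs of activity above the 99th percentile of the wideband noise floor.

    The noise floor is the distribution of the instantaneous rectified
    amplitude within the lowest-decile RMS 1-s windows; its 99th percentile is
    the threshold. Runs are detected on the smoothed (moving-average,
    ``smooth_win``) rectified amplitude, which for pure noise concentrates
    well below the instantaneous 99th percentile, so stationary noise yields
    almost no epochs while genuine oscillatory bursts several times the floor
    cross it within one smoothing window. Gaps < ``merge_gap`` are merged and
    runs < ``min_duration`` discarded.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10 * fs:
        raise ValueError("need at least 10 s of signal to estimate the noise floor")
    win = max(int(round(smooth_win * fs)), 1)
    amp = np.convolve(np.abs(x), np.ones(win) / win, mode="same")

    wlen = int(round(floor_window * fs))
    n_win = x.size // wlen
    seg = x[: n_win * wlen].reshape(n_win, wlen)
    rms = np.sqrt((seg ** 2).mean(axis=1))
    k = max(int(np.ceil(floor_decile * n_win)), 1)
    quiet = np.argsort(rms)[:k]
    floor_samples = np.abs(np.concatenate([seg[i] for i in quiet]))
    threshold = float(np.percentile(floor_samples, 99))

    above = amp > threshold
    # merge short gaps
    idx = np.flatnonzero(above)
    intervals: list[tuple[float, float]] = []
    if idx.size:
        gaps = np.flatnonzero(np.diff(idx) > merge_gap * fs)
        starts = np.r_[idx[0], idx[gaps + 1]]
        ends = np.r_[idx[gaps], idx[-1]] + 1
        for a, b in zip(starts, ends):
            if (b - a) / fs >= min_duration:
                intervals.append((a / fs, b / fs))

    durs = np.array([b - a for a, b in intervals])
    if intervals:
        mask = np.zeros(x.size, dtype=bool)
        for a, b in intervals:
            mask[int(a * fs) : int(b * fs)] = True
        wb = float((x[mask] ** 2).mean())
    else:
        wb = 0.0
    return OscillatoryEpochs(
        intervals=intervals,
        threshold=threshold,
        mean_duration=float(durs.mean()) if durs.size else 0.0,
        total_duration=float(durs.sum()),
        wideband_power=wb,
    )


# ---------------------------------------------------------------------------
# Twitch-triggered averages
# ---------------------------------------------------------------------------

def twitch_triggered_spectrogram(
    ws: WaveletSpectrogram,
    twitches: np.ndarray,
    window: float = 1.0,
    zero_window: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Average z-scored spectrogram around twitch times.

    Each per-twitch slice is z-scored per frequency row over the window, then
    averaged; lags within ``zero_window`` of the twitch are set to zero to
    avoid movement-artifact contamination. Returns (freqs x lags matrix,
    lag vector in s). Twitches whose window extends past the record are
    excluded; an error is raised if none remain.
    """
    half = int(round(window * ws.fs))
    n = ws.magnitude.shape[1]
    slices = []
    for t in np.asarray(twitches, dtype=float):
        i = int(round(t * ws.fs))
        if i - half < 0 or i + half + 1 > n:
            continue
        sl = ws.magnitude[:, i - half : i + half + 1]
        mu = sl.mean(axis=1, keepdims=True)
        sd = sl.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        slices.append((sl - mu) / sd)
    if not slices:
        raise ValueError("no twitch lies fully inside the record")
    avg = np.mean(slices, axis=0)
    lags = np.arange(-half, half + 1) / ws.fs
    avg[:, np.abs(lags) <= zero_window] = 0.0
    return avg, lags


@dataclass
class CrossCorrelogram:
    lags: np.ndarray  # bin centers, s
    counts: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    exceeds: np.ndarray  # per-bin flag: counts outside the shuffled 95% CI


def twitch_event_xcorr(
    twitches: np.ndarray,
    events: np.ndarray,
    lag_range: float = 2.0,
    bin_width: float = 0.1,
    n_shuffle: int = 500,
    seed: int = 0,
) -> CrossCorrelogram:
    """Cross-correlogram of event times around twitch times with shuffle CI."""
    twitches = np.asarray(twitches, dtype=float)
    events = np.asarray(events, dtype=float)
    if twitches.size == 0 or events.size == 0:
        raise ValueError("both series must be non-empty")
    if n_shuffle <= 0:
        raise ValueError("n_shuffle must be positive")
    edges = np.arange(-lag_range, lag_range + bin_width / 2, bin_width)
    lags = (edges[:-1] + edges[1:]) / 2

    def xcorr(ev: np.ndarray) -> np.ndarray:
        diffs = []
        for t in twitches:
            d = ev[(ev >= t - lag_range) & (ev <= t + lag_range)] - t
            diffs.append(d)
        d = np.concatenate(diffs) if diffs else np.empty(0)
        return np.histogram(d, bins=edges)[0]

    counts = xcorr(events)
    rng = np.random.default_rng(seed)
    lo, hi = min(twitches.min(), events.min()), max(twitches.max(), events.max())
    null = np.empty((n_shuffle, lags.size))
    for k in range(n_shuffle):
        null[k] = xcorr(np.sort(rng.uniform(lo, hi, events.size)))
    ci_low = np.percentile(null, 2.5, axis=0)
    ci_high = np.percentile(null, 97.5, axis=0)
    exceeds = (counts > ci_high) | (counts < ci_low)
    return CrossCorrelogram(lags=lags, counts=counts, ci_low=ci_low, ci_high=ci_high, exceeds=exceeds)


# ---------------------------------------------------------------------------
# Aperiodic exponent
# ---------------------------------------------------------------------------

def aperiodic_exponent(
    freqs: np.ndarray,
    powers: np.ndarray,
    band: tuple[float, float] = (2.0, 40.0),
    peak_sd: float = 2.0,
) -> AperiodicFit:
    """Power-law exponent of the aperiodic PSD component.

    Robust (Huber) regression of log power on log frequency within ``band``,
    after masking narrowband peaks (points whose residual from an initial
    robust fit exceeds ``peak_sd`` robust SDs upward). The exponent is the
    negative slope; a full joint peak+aperiodic model is deliberately not
    re-implemented.
    """
    freqs = np.asarray(freqs, dtype=float)
    powers = np.asarray(powers, dtype=float)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if sel.sum() < 10:
        raise ValueError("need at least 10 frequencies within the fit band")
    if np.any(powers[sel] <= 0):
        raise ValueError("powers must be positive within the fit band")
    lf = np.log10(freqs[sel])
    lp = np.log10(powers[sel])

    def huber_fit(x, y):
        X = sm.add_constant(x)
        res = sm.RLM(y, X, M=sm.robust.norms.HuberT()).fit()
        return res.params  # (intercept, slope)

    params = huber_fit(lf, lp)
    resid = lp - (params[0] + params[1] * lf)
    sd = np.median(np.abs(resid)) / 0.6745
    mask = resid > peak_sd * max(sd, 1e-12)  # upward outliers = narrowband peaks
    if mask.any() and (~mask).sum() >= 10:
        params = huber_fit(lf[~mask], lp[~mask])
    fitted = params[0] + params[1] * lf[~mask]
    ss_res = float(((lp[~mask] - fitted) ** 2).sum())
    ss_tot = float(((lp[~mask] - lp[~mask].mean()) ** 2).sum())
    r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AperiodicFit(
        exponent=float(-params[1]),
        offset=float(params[0]),
        band=band,
        r_squared=r2,
        masked=mask,
    )
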