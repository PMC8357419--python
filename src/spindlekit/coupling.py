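"""Event-locked amplitude-amplitude cross-frequency coupling.

A comodulogram is the matrix of correlations between wavelet magnitude time
series at pairs of frequencies, pooled over 4-s windows centered on detected
spindle-band events. Magnitudes are smoothed with a Gaussian whose width is
matched to each row's frequency (sigma = 2 cycles), log-transformed, and
correlated (Pearson by default). Because neighboring samples of a wavelet
magnitude series are strongly autocorrelated, significance uses an effective
sample size (Pyper-Peterman/Bartlett correction) before Bonferroni-Holm.

The coupling curve sums the comodulogram columns belonging to the spindle
band (10-20 Hz); local maxima outside the spindle band are retained when
prominent (prominence > 0.75) and narrow (default relative rule: width
< center frequency, i.e. quality factor > 1; the literal reading
width < 1/f_c is available via ``width_rule='inverse'``). Each retained
peak carries a coupling index (value x prominence) / width, and band-limited
coupling is summarized by the trapezoidal AUC of the curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .spectral import gabor_spectrogram

__all__ = [
    "Comodulogram",
    "CouplingPeak",
    "CouplingCurve",
    "comodulogram",
    "spindle_coupling_curve",
    "detect_coupling_peaks",
    "coupling_auc",
    "default_comod_grid",
]

SPINDLE_COLUMNS = (10.0, 20.0)
PEAK_EXCLUDE_BAND = (8.0, 25.0)  # spindle self-block excluded from peak search
LINE_NOISE_HZ = 60.0
LINE_NOISE_HALF_WIDTH = 2.0


def default_comod_grid(fmin: float = 1.0, fmax: float = 100.0, n: int = 40) -> np.ndarray:
    """Log-spaced comodulogram grid with 60 +- 2 Hz line-noise rows dropped."""
    g = np.geomspace(fmin, fmax, n)
    keep = np.abs(g - LINE_NOISE_HZ) > LINE_NOISE_HALF_WIDTH
    return g[keep]


@dataclass
class Comodulogram:
    corr: np.ndarray  # freq x freq, symmetric, unit diagonal
    freqs: np.ndarray
    significant: np.ndarray  # boolean mask after Bonferroni-Holm
    n_events: int
    window: float


@dataclass
class CouplingPeak:
    f_c: float  # center frequency, Hz
    value: float
    prominence: float
    width: float  # Hz at half prominence
    coupling_index: float


@dataclass
class CouplingCurve:
    freqs: np.ndarray
    curve: np.ndarray
    peaks: list[CouplingPeak] = field(default_factory=list)
    search_mask: np.ndarray | None = None  # rows eligible for peak detection


def _autocorr_rows(data: np.ndarray, max_lag: int) -> np.ndarray:
    """Autocorrelation of each row at lags 1..max_lag (FFT-based)."""
    n = data.shape[1]
    centered = data - data.mean(axis=1, keepdims=True)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), nfft, axis=1)[:, : max_lag + 1]
    denom = acov[:, :1].copy()
    denom[denom == 0] = 1.0
    return (acov / denom)[:, 1:]


def _effective_n_matrix(data: np.ndarray, max_lag: int) -> np.ndarray:
    """Pyper-Peterman effective sample size for every row pair."""
    n = data.shape[1]
    rho = _autocorr_rows(data, min(max_lag, n - 2))
    s = 1.0 + 2.0 * (rho @ rho.T)
    return np.clip(n / np.maximum(s, 1.0), 4.0, n)


def comodulogram(
    lfp: np.ndarray,
    fs: float,
    event_times: np.ndarray,
    window: float = 4.0,
    freqs: np.ndarray | None = None,
    n_cycles: float = 12.0,
    method: str = "pearson",
    alpha: float = 0.05,
    whiten: bool = True,
) -> Comodulogram:
    """Amplitude comodulogram over event-centered windows.

    ``event_times`` are event midpoints in seconds; windows extending past the
    record are dropped. Requires at least five usable events. The signal is
    AR(1)-whitened by default and the wavelets use 12 cycles: narrow-band
    kernels keep the spectral side-lobes of a strong oscillation from leaking
    coherent amplitude into distant rows, which would smear genuinely
    band-limited coupling across the whole comodulogram.
    """
    event_times = np.asarray(event_times, dtype=float)
    if freqs is None:
        freqs = default_comod_grid(fmax=min(100.0, 0.45 * fs))
    freqs = np.asarray(freqs, dtype=float)
    ws = gabor_spectrogram(np.asarray(lfp, dtype=float), fs, freqs, n_cycles=n_cycles, whiten=whiten)

    # frequency-matched Gaussian smoothing: sigma = 2 cycles of the row freq
    mags = np.empty_like(ws.magnitude)
    for i, f in enumerate(freqs):
        sigma = max(2.0 / f * fs, 1.0)
        half = int(np.ceil(3 * sigma))
        t = np.arange(-half, half + 1)
        g = np.exp(-(t ** 2) / (2 * sigma ** 2))
        g /= g.sum()
        mags[i] = sps.fftconvolve(ws.magnitude[i], g, mode="same")

    half_w = int(round(window / 2 * fs))
    n = mags.shape[1]
    cols = []
    kept = 0
    for t in event_times:
        c = int(round(t * fs))
        if c - half_w < 0 or c + half_w > n:
            continue
        cols.append(mags[:, c - half_w : c + half_w])
        kept += 1
    if kept < 5:
        raise ValueError(f"need at least 5 events fully inside the record (got {kept})")
    pooled = np.log(np.concatenate(cols, axis=1) + 1e-12)

    nf = freqs.size
    max_lag = int(round(2 * fs / freqs[0]))
    if method == "spearman":
        data = np.apply_along_axis(stats.rankdata, 1, pooled)
    else:
        data = pooled
    corr = np.corrcoef(data)
    np.fill_diagonal(corr, 1.0)
    n_eff = _effective_n_matrix(data, max_lag)
    iu, ju = np.triu_indices(nf, k=1)
    r = corr[iu, ju]
    df = np.maximum(n_eff[iu, ju] - 2, 2.0)
    t_stat = np.abs(r) * np.sqrt(df / np.maximum(1 - r ** 2, 1e-12))
    pvals = 2 * stats.t.sf(t_stat, df)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    sig = np.zeros((nf, nf), dtype=bool)
    sig[iu, ju] = reject
    sig |= sig.T
    return Comodulogram(corr=corr, freqs=freqs, significant=sig, n_events=kept, window=window)


def spindle_coupling_curve(
    cmg: Comodulogram,
    column_band: tuple[float, float] = SPINDLE_COLUMNS,
    exclude_band: tuple[float, float] = PEAK_EXCLUDE_BAND,
) -> CouplingCurve:
    """Summate spindle-band comodulogram columns into a coupling curve."""
    cols = (cmg.freqs >= column_band[0]) & (cmg.freqs <= column_band[1])
    if not cols.any():
        raise ValueError("comodulogram grid lacks spindle-band (10-20 Hz) support")
    curve = cmg.corr[:, cols].sum(axis=1)
    # peak search covers frequencies above the spindle band only: the
    # spindle self-block is trivially coupled, and sub-spindle rows have too
    # few independent amplitude fluctuations per 4-s window for stable peaks
    search = cmg.freqs > exclude_band[1]
    return CouplingCurve(freqs=cmg.freqs.copy(), curve=curve, search_mask=search)


def detect_coupling_peaks(
    cc: CouplingCurve,
    prominence_threshold: float = 0.75,
    width_rule: str = "relative",
) -> list[CouplingPeak]:
    """Retain prominent, narrow local maxima of the coupling curve.

    ``width_rule='relative'`` keeps peaks with half-prominence width < f_c
    (quality factor > 1); ``'inverse'`` applies the literal width < 1/f_c.
    """
    if cc.curve.size < 5:
        raise ValueError("curve too short for peak detection")
    idx, props = sps.find_peaks(cc.curve, prominence=0.0)
    widths_samp, _, lips, rips = sps.peak_widths(cc.curve, idx, rel_height=0.5)
    grid = np.arange(cc.freqs.size)
    peaks: list[CouplingPeak] = []
    for k, i in enumerate(idx):
        if cc.search_mask is not None and not cc.search_mask[i]:
            continue
        f_c = float(cc.freqs[i])
        prom = float(props["prominences"][k])
        # convert half-prominence interpolated positions to Hz on the grid
        f_left = float(np.interp(lips[k], grid, cc.freqs))
        f_right = float(np.interp(rips[k], grid, cc.freqs))
        width = f_right - f_left
        if prom <= prominence_threshold:
            continue
        limit = f_c if width_rule == "relative" else 1.0 / f_c
        if width >= limit:
            continue
        value = float(cc.curve[i])
        peaks.append(
            CouplingPeak(
                f_c=f_c,
                value=value,
                prominence=prom,
                width=width,
                coupling_index=coupling_index(value, prom, width),
            )
        )
    cc.peaks = peaks
    return peaks


def coupling_index(value: float, prominence: float, width: float) -> float:
    """Wide-band coupling index: (peak value x peak prominence) / peak width."""
    if width <= 0:
        raise ValueError("peak width must be positive")
    return value * prominence / width


def coupling_auc(cc: CouplingCurve, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the coupling curve over ``band`` (Hz)."""
    if band[0] < cc.freqs[0] or band[1] > cc.freqs[-1]:
        raise ValueError("band outside the curve's frequency support")
    fgrid = np.linspace(band[0], band[1], 101)
    vals = np.interp(fgrid, cc.freqs, cc.curve)
    return float(np.trapezoid(vals, fgrid))
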