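"""Multi-unit spiking: detection, artifact/duplicate removal, ISI,
autocorrelograms with convolution-based confidence bands, event-triggered
rates, and spindle-phase locking.

Spikes are negative threshold crossings of the 250-2500 Hz band at four times
the per-channel noise floor (median(|x|)/0.6745). Detections coincident
(within +-0.5 ms) across channels farther apart than a physiological spike
footprint (~300 um) are treated as artifacts and removed everywhere;
within-zone detections closer than 2 ms are collapsed onto the first.

The autocorrelogram confidence band follows the partially hollow convolution
approach: the expected count per 10 ms lag bin is the ACG smoothed with a
hollow Gaussian kernel (center weight removed), and the pointwise 95% band
comes from Poisson quantiles at that expectation. Phase locking extracts the
Hilbert phase of the 9-16 Hz band (after downsampling the LFP to 125 Hz) at
spike times inside detected events, with a maximum-likelihood von Mises
concentration (kappa) and a Rayleigh (or Kuiper) uniformity test;
significance requires kappa > 0.1 and p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

__all__ = [
    "SpikeTrain",
    "Autocorrelogram",
    "PSTHResult",
    "PhaseLockingResult",
    "detect_spikes",
    "deduplicate",
    "isi",
    "autocorrelogram_ci",
    "event_triggered_rate",
    "phase_locking",
    "vonmises_kappa_mle",
]

SPIKE_BAND = (250.0, 2500.0)
THRESHOLD_FACTOR = 4.0
ARTIFACT_DISTANCE_UM = 300.0
ARTIFACT_COINCIDENCE_S = 0.0005
DEDUP_WINDOW_S = 0.002
BURST_WINDOW_S = 0.05
SUPPRESSION_WINDOW_S = (0.05, 0.5)


@dataclass
class SpikeTrain:
    times: np.ndarray  # s, strictly increasing after dedup
    zone: str
    source_channels: tuple[int, ...] = ()
    noise_floor: dict[int, float] = field(default_factory=dict)  # uV per channel

    @property
    def n(self) -> int:
        return self.times.size


@dataclass
class Autocorrelogram:
    lags: np.ndarray  # bin centers, s
    counts: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    expected: np.ndarray
    burst_excess: float  # significant positive mass, |lag| < 50 ms
    suppression_excess: float  # significant negative mass, 50-500 ms


@dataclass
class PSTHResult:
    lags: np.ndarray  # bin centers relative to event onset, s
    rate: np.ndarray  # normalized to baseline rate
    ci_low: np.ndarray
    ci_high: np.ndarray
    baseline_rate: float  # Hz
    undefined: bool = False  # no baseline spikes: normalization impossible


@dataclass
class PhaseLockingResult:
    phases: np.ndarray  # rad, (-pi, pi]
    kappa: float
    p_value: float
    preferred_phase: float
    significant: bool
    histogram: np.ndarray  # counts in pi/24 bins
    bin_edges: np.ndarray
    test: str = "rayleigh"


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _channel_distance(p: tuple[float, float], q: tuple[float, float]) -> float:
    return float(np.hypot(p[0] - q[0], p[1] - q[1]))


def deduplicate(times: np.ndarray, window: float = DEDUP_WINDOW_S) -> np.ndarray:
    """Collapse detections closer than ``window`` onto the first (idempotent)."""
    times = np.sort(np.asarray(times, dtype=float))
    if times.size == 0:
        return times
    keep = [0]
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last >= window:
            keep.append(i)
            last = times[i]
    return times[keep]


def detect_spikes(
    highband: np.ndarray,
    fs: float,
    positions: list[tuple[float, float]],
    zones: dict[int, str],
    threshold_factor: float = THRESHOLD_FACTOR,
    prefiltered: bool = False,
) -> dict[str, SpikeTrain]:
    """Detect multi-unit spikes per zone from multichannel high-band signal.

    ``zones`` maps channel index to a zone tag; channels absent from the map
    are ignored. Returns one deduplicated SpikeTrain per zone.
    """
    x = np.atleast_2d(np.asarray(highband, dtype=float))
    if not zones:
        raise ValueError("no channel is assigned to a zone")
    for ch in zones:
        if ch >= x.shape[0]:
            raise ValueError(f"zone map references channel {ch} beyond the signal")
    if not prefiltered:
        sos = sps.butter(
            4, [SPIKE_BAND[0], min(SPIKE_BAND[1], 0.45 * fs)], btype="bandpass", fs=fs, output="sos"
        )
        x = sps.sosfiltfilt(sos, x, axis=1)

    detections: list[tuple[float, int]] = []
    floors: dict[int, float] = {}
    for ch in sorted(zones):
        sig = x[ch]
        floor = float(np.median(np.abs(sig)) / 0.6745)
        floors[ch] = floor
        idx, _ = sps.find_peaks(-sig, height=threshold_factor * floor)
        detections.extend((i / fs, ch) for i in idx)
    detections.sort()

    # cross-distance artifact removal: coincident detections on channels
    # farther apart than a physiological spike footprint kill both
    times = np.array([t for t, _ in detections])
    chans = np.array([c for _, c in detections])
    bad = np.zeros(times.size, dtype=bool)
    j = 0
    for i in range(times.size):
        k = i + 1
        while k < times.size and times[k] - times[i] <= ARTIFACT_COINCIDENCE_S:
            d = _channel_distance(positions[chans[i]], positions[chans[k]])
            if d > ARTIFACT_DISTANCE_UM:
                bad[i] = bad[k] = True
            k += 1
    times, chans = times[~bad], chans[~bad]

    out: dict[str, SpikeTrain] = {}
    for zone in sorted(set(zones.values())):
        zone_chs = tuple(sorted(c for c, z in zones.items() if z == zone))
        zt = times[np.isin(chans, zone_chs)]
        out[zone] = SpikeTrain(
            times=deduplicate(zt),
            zone=zone,
            source_channels=zone_chs,
            noise_floor={c: floors[c] for c in zone_chs},
        )
    return out


# ---------------------------------------------------------------------------
# ISI / autocorrelogram
# ---------------------------------------------------------------------------

def isi(train: SpikeTrain) -> np.ndarray:
    """Inter-spike intervals (s) between sorted spike times within the zone."""
    if train.n < 2:
        raise ValueError("need at least two spikes")
    return np.diff(np.sort(train.times))


def autocorrelogram_ci(
    train: SpikeTrain,
    bin_width: float = 0.01,
    window: float = 0.5,
    kernel_sigma_bins: float = 2.0,
    min_spikes: int = 50,
) -> Autocorrelogram:
    """Spike-time autocorrelogram with a 95% convolution confidence band."""
    if train.n < min_spikes:
        raise ValueError(f"need at least {min_spikes} spikes")
    t = np.sort(train.times)
    edges = np.arange(-window, window + bin_width / 2, bin_width)
    lags = (edges[:-1] + edges[1:]) / 2
    diffs = []
    for i, ti in enumerate(t):
        j = np.searchsorted(t, ti + window, side="right")
        k = np.searchsorted(t, ti - window, side="left")
        d = t[k:j] - ti
        d = d[d != 0]
        diffs.append(d)
    alld = np.concatenate(diffs) if diffs else np.empty(0)
    counts = np.histogram(alld, bins=edges)[0].astype(float)
    center = np.argmin(np.abs(lags))

    # partially hollow Gaussian smoothing: expected count per bin
    half = int(np.ceil(4 * kernel_sigma_bins))
    kk = np.arange(-half, half + 1)
    g = np.exp(-(kk ** 2) / (2 * kernel_sigma_bins ** 2))
    g[half] = 0.0  # hollow center
    g /= g.sum()
    # renormalize at the edges where the kernel is truncated
    expected = np.convolve(counts, g, mode="same") / np.convolve(np.ones_like(counts), g, mode="same")

    # pointwise 95% band: Poisson quantiles, widened for the sampling
    # variance of the smoothed expectation itself (sum g^2)
    inflation = 1.0 + float(g @ g)
    z = stats.norm.ppf(0.975) * np.sqrt(inflation)
    p_lo, p_hi = stats.norm.cdf(-z), stats.norm.cdf(z)
    mu = np.maximum(expected, 1e-9)
    ci_low = stats.poisson.ppf(p_lo, mu)
    ci_high = stats.poisson.ppf(p_hi, mu)

    abs_lag = np.abs(lags)
    burst_bins = (abs_lag > 1e-12) & (abs_lag < BURST_WINDOW_S)
    burst_bins[center] = False
    supp_bins = (abs_lag >= SUPPRESSION_WINDOW_S[0]) & (abs_lag <= SUPPRESSION_WINDOW_S[1])
    burst_excess = float(np.maximum(counts - ci_high, 0)[burst_bins].sum())
    suppression_excess = float(np.maximum(ci_low - counts, 0)[supp_bins].sum())
    return Autocorrelogram(
        lags=lags,
        counts=counts,
        ci_low=ci_low,
        ci_high=ci_high,
        expected=expected,
        burst_excess=burst_excess,
        suppression_excess=suppression_excess,
    )


# ---------------------------------------------------------------------------
# Event-triggered rate
# ---------------------------------------------------------------------------

def event_triggered_rate(
    train: SpikeTrain,
    event_onsets: np.ndarray,
    bin_width: float = 0.05,
    window: tuple[float, float] = (-1.5, 2.0),
    baseline: tuple[float, float] = (-1.0, -0.2),
    n_shuffle: int = 200,
    seed: int = 0,
) -> PSTHResult:
    """Peri-event spike rate normalized to the pre-event baseline rate.

    The 95% band comes from ``n_shuffle`` resamples with spike times redrawn
    uniformly over the recording span, each normalized the same way.
    """
    event_onsets = np.asarray(event_onsets, dtype=float)
    if event_onsets.size < 5:
        raise ValueError("need at least 5 events")
    t = np.sort(train.times)
    edges = np.arange(window[0], window[1] + bin_width / 2, bin_width)
    lags = (edges[:-1] + edges[1:]) / 2

    def psth(times: np.ndarray) -> tuple[np.ndarray, float]:
        rel = []
        for e in event_onsets:
            d = times[(times >= e + window[0]) & (times <= e + window[1])] - e
            rel.append(d)
        rel = np.concatenate(rel) if rel else np.empty(0)
        counts = np.histogram(rel, bins=edges)[0]
        rate = counts / (event_onsets.size * bin_width)
        base = rel[(rel >= baseline[0]) & (rel < baseline[1])]
        base_rate = base.size / (event_onsets.size * (baseline[1] - baseline[0]))
        return rate, base_rate

    rate, base_rate = psth(t)
    if base_rate == 0:
        return PSTHResult(
            lags=lags,
            rate=np.full(lags.size, np.nan),
            ci_low=np.full(lags.size, np.nan),
            ci_high=np.full(lags.size, np.nan),
            baseline_rate=0.0,
            undefined=True,
        )
    norm = rate / base_rate

    rng = np.random.default_rng(seed)
    span = (t.min(), t.max())
    null = np.empty((n_shuffle, lags.size))
    for k in range(n_shuffle):
        shuf = np.sort(rng.uniform(span[0], span[1], t.size))
        r, b = psth(shuf)
        null[k] = r / b if b > 0 else np.nan
    ci_low = np.nanpercentile(null, 2.5, axis=0)
    ci_high = np.nanpercentile(null, 97.5, axis=0)
    return PSTHResult(
        lags=lags, rate=norm, ci_low=ci_low, ci_high=ci_high, baseline_rate=base_rate
    )


# ---------------------------------------------------------------------------
# Phase locking
# ---------------------------------------------------------------------------

def vonmises_kappa_mle(phases: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood von Mises (kappa, preferred phase) from a sample.

    Uses the Best & Fisher approximation to invert the mean resultant length.
    """
    z = np.exp(1j * np.asarray(phases, dtype=float))
    r = float(np.abs(z.mean()))
    mu = float(np.angle(z.mean()))
    if r < 0.53:
        kappa = 2 * r + r ** 3 + 5 * r ** 5 / 6
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        kappa = 1 / (r ** 3 - 4 * r ** 2 + 3 * r)
    return float(kappa), mu


def _kuiper_p(phases: np.ndarray) -> float:
    """Kuiper test of circular uniformity (asymptotic p)."""
    u = np.sort((np.asarray(phases) % (2 * np.pi)) / (2 * np.pi))
    n = u.size
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    v = (d_plus + d_minus) * (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n))
    if v < 0.4:
        return 1.0
    j = np.arange(1, 101)
    terms = (4 * j ** 2 * v ** 2 - 1) * np.exp(-2 * j ** 2 * v ** 2)
    return float(np.clip(2 * terms.sum(), 0.0, 1.0))


def rayleigh_p(phases: np.ndarray) -> float:
    """Rayleigh test of circular uniformity."""
    from pingouin import circ_rayleigh

    _, p = circ_rayleigh(np.asarray(phases, dtype=float))
    return float(p)


def phase_locking(
    train: SpikeTrain,
    lfp: np.ndarray,
    fs: float,
    event_intervals: list[tuple[float, float]],
    band: tuple[float, float] = (9.0, 16.0),
    fs_phase: float = 125.0,
    min_spikes: int = 20,
    test: str = "rayleigh",
    kappa_threshold: float = 0.1,
    alpha: float = 0.05,
) -> PhaseLockingResult:
    """Phase locking of spikes (inside events) to the spindle-band LFP phase.

    Phase convention: 0 at the band-passed waveform peak, +-pi at the trough.
    """
    if not event_intervals:
        raise ValueError("no event intervals supplied")
    # downsample then narrowly band-pass; Hilbert phase on the full trace
    dec = int(round(fs / fs_phase))
    low = sps.resample_poly(np.asarray(lfp, dtype=float), 1, dec)
    fs_d = fs / dec
    sos = sps.butter(4, [band[0], band[1]], btype="bandpass", fs=fs_d, output="sos")
    filt = sps.sosfiltfilt(sos, low)
    analytic = sps.hilbert(filt)
    t_grid = np.arange(low.size) / fs_d

    spikes = np.sort(train.times)
    in_event = np.zeros(spikes.size, dtype=bool)
    for a, b in event_intervals:
        in_event |= (spikes >= a) & (spikes < b)
    spikes = spikes[in_event]
    if spikes.size < min_spikes:
        raise ValueError(f"need at least {min_spikes} spikes within events (got {spikes.size})")

    # interpolate the analytic signal at spike times, then take the angle
    re = np.interp(spikes, t_grid, analytic.real)
    im = np.interp(spikes, t_grid, analytic.imag)
    phases = np.angle(re + 1j * im)

    kappa, mu = vonmises_kappa_mle(phases)
    p = rayleigh_p(phases) if test == "rayleigh" else _kuiper_p(phases)
    nbins = 48  # pi/24 bins
    edges = np.linspace(-np.pi, np.pi, nbins + 1)
    hist = np.histogram(phases, bins=edges)[0]
    return PhaseLockingResult(
        phases=phases,
        kappa=kappa,
        p_value=p,
        preferred_phase=mu,
        significant=bool(kappa > kappa_threshold and p < alpha),
        histogram=hist,
        bin_edges=edges,
        test=test,
    )
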