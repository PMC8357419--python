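# Methods

This note documents the models, parameter choices and numerical conventions
behind spindlekit, what the synthetic generators do and do not emulate, and
the design decisions taken where the procedure was genuinely open.

## Conventions

Time is in seconds, intervals are half-open [start, end), sample indices are
0-based, and microvolts are the canonical amplitude unit after acquisition
gain. Raw multichannel binary is frame-major interleaved int16 (the
Intan/Neuroscope convention) with a JSON sidecar carrying labels, geometry,
sampling rate and — because it is hardware-specific — a mandatory gain in
µV/bit. Event tables store both seconds and sample indices. All stochastic
stages take an explicit seed; the pipeline derives per-stage sub-seeds from
one master seed via `numpy.random.SeedSequence`, so a config + seed pair
reproduces every output byte for byte.

## Wavelet analysis

Time–frequency decomposition uses analytic Gabor (complex Morlet) kernels
with a 5-cycle Gaussian envelope on a log-spaced 1–100 Hz grid (53 points)
by default. Kernels are amplitude-calibrated (a unit sinusoid at a grid
frequency yields magnitude ≈ 1), and each kernel's equivalent noise bandwidth
is stored so magnitudes can be converted to a one-sided PSD estimate; for
stationary noise the integrated wavelet PSD agrees with band variance within
~7% (asserted at 15%). Signals are AR(1)-whitened before spectral display and
before PAR band powers: the lag-1 regression coefficient is estimated from
the signal and `y[t] = x[t] − φ x[t−1]` flattens the steep 1/f background of
developing cortex. Whitening is skipped only where a test requires raw
amplitudes.

## Spindle-band event detection

Band powers are means of squared wavelet magnitudes over a few log-spaced
frequencies per band (6 in 8–25 Hz, 3 in the low band, 6 in 30–80 Hz). The
detector thresholds spindle-band power at median + 3 × median(|Pspi|)/0.6745
computed within the sleep mask — the multiplier is exposed per age group in
the configuration because signal-to-noise differs across preparations — and
keeps PAR > −0.1 runs of 0.3–5 s with a positive PAR peak. Event boundaries
are the full PAR run rather than the power-threshold run; with 5× background
events this recovers injected boundaries with a mean error of ~70 ms at
1250 Hz. Because both PAR and the MAD threshold are homogeneous in signal
scale, detections are invariant to rescaling the whole recording.

For human subjects younger than 40 post-gestational weeks the low band moves
to 2–6 Hz, which keeps the slow component of delta brushes from counting
against the spindle band.

## Characterization

Power: 4th-order zero-phase Butterworth 8–25 Hz, Hilbert envelope, median
over the event, computed on a 1-s context-padded segment so filter
transients stay outside the interval. Spatial extent counts the reference
channel in the numerator and divides by the number of functional channels;
co-occurrence requires > 300 ms interval intersection and ≤ 50 ms midpoint
separation. Sharpness uses the raw trace at ±8 ms around extrema bracketed by
zero-crossings of the broadly filtered (5–30 Hz) signal; the 8 ms offset is
kept as specified even though it is not half a period across the whole band,
and is configurable. Peaks are maxima between a rising and the next falling
zero-crossing; troughs are minima between a falling and the next rising
crossing (the symmetric reading — inverting the signal exactly reciprocates
the ESR, which the tests assert to 1e−6).

## Cross-frequency coupling

Comodulograms pool 4-s event-centered windows of wavelet magnitudes, each row
smoothed with a Gaussian of σ = 2 cycles of its frequency, log-transformed
and Pearson-correlated (Spearman available). Two numerical choices matter:

- **Narrow-band kernels (12 cycles) and AR(1) whitening.** With 5-cycle
  kernels the spectral side-lobes of a strong oscillation leak coherent
  amplitude into rows tens of Hz away; since correlation is scale-free, even
  1% leakage on a weak background row reads as strong coupling, smearing a
  genuinely band-limited interaction across the grid. Twelve cycles plus
  whitening confine a 50 Hz envelope-shared carrier to ±2 grid steps.
- **Effective sample size.** Wavelet magnitude series are strongly
  autocorrelated, so Pearson p-values at the raw sample count are badly
  anticonservative. Significance uses the Pyper–Peterman/Bartlett effective
  sample size (computed from the two rows' autocorrelation functions) before
  Bonferroni–Holm correction.

The coupling curve sums the 10–20 Hz columns. Peak search is restricted to
frequencies above the spindle band: the self-block is trivially coupled, and
rows below ~8 Hz have too few independent amplitude fluctuations per 4-s
window for stable peak estimates. Retained peaks need prominence > 0.75 and a
half-prominence width smaller than the center frequency (quality factor > 1);
the literal width < 1/f_c reading is available via `width_rule="inverse"` but
rejects essentially everything (sub-0.1 Hz widths at gamma frequencies). AUC
is a trapezoidal integral of the curve over a stated band on an interpolated
grid. Rows within ±2 Hz of 60 Hz are dropped from the default grid to avoid
line-noise artifacts.

## Spiking statistics

The noise floor per channel is median(|x|)/0.6745 of the 250–2500 Hz band;
spikes are negative peaks beyond 4 floors. Detections coincident within
±0.5 ms on channels more than 300 µm apart are treated as non-physiological
and removed from all channels; within a zone, detections < 2 ms apart
collapse onto the first (idempotent).

The autocorrelogram band is a calibrated form of the convolution method: the
expected count per 10 ms bin is the ACG smoothed with a hollow Gaussian
kernel (σ = 2 bins, center weight removed, edge-renormalized), and the 95%
band takes Poisson quantiles at levels widened by the sampling variance of
the smoothed expectation itself (factor 1 + Σg²). On homogeneous Poisson
trains at neonatal multi-unit rates this yields 3–6% of bins outside the band
across rates 2–20 Hz. Burst excess sums counts above the band at |lag| <
50 ms; suppression excess sums shortfall below it at 50–500 ms.

Peri-event rates use 50 ms bins over (−1.5, 2) s around event onsets,
normalized by the rate in a (−1.0, −0.2) s pre-event baseline window, with a
95% band from spike-time shuffles (uniform redraw over the recording span). A
zero baseline flags the normalized PSTH undefined rather than dividing.

Phase locking downsamples the LFP to 125 Hz, band-passes 9–16 Hz, and
interpolates the complex analytic signal at spike times (spikes restricted to
event intervals; ≥ 20 required). Phase 0 is the band-passed peak, ±π the
trough. κ comes from the Best–Fisher inversion of the mean resultant length;
the uniformity p-value is a Rayleigh test by default (a Kuiper alternative
with asymptotic p is implemented, chosen by argument); significance requires
both κ > 0.1 and p < 0.05, so large samples cannot rescue negligible
concentrations.

## State scoring

The EMG is high-pass filtered at 300 Hz. Threshold statistics (mean + k·SD,
k ∈ [1.5, 3.5], default 2.5) are computed on the instantaneous rectified
signal — whose distribution is wide — while runs are detected on a 100-ms
moving-RMS envelope, whose quiescent fluctuations stay well below that
threshold; this prevents stationary atonia noise from generating phantom
twitches. Supra-threshold runs ≥ 1.5 s are wake, shorter bursts flanked by
atonia are twitches, sub-threshold runs ≥ 2 s are atonia; atonia blocks
containing twitches are active sleep, twitch-free blocks ≥ 10 s quiet sleep.
Runs failing both duration rules merge into agreeing flanks, else stay
unlabeled. The behavioral-quiescence video channel of a real experiment is
replaced by an optional external mask; absent one, EMG silence alone defines
quiescence.

## Oscillatory epochs and the aperiodic fit

The wideband noise floor is the distribution of instantaneous rectified
amplitude within the lowest-decile RMS 1-s windows; its 99th percentile
thresholds the 100-ms-smoothed amplitude, with < 100 ms gaps merged and
< 100 ms epochs discarded. Thresholding the smoothed trace against the
instantaneous-amplitude percentile makes stationary noise yield essentially
no epochs while bursts a few times the floor are recovered with < 100 ms
boundary error; the threshold is amplitude-equivariant. The aperiodic
exponent is the negative slope of a Huber-robust log–log fit over 2–40 Hz
after masking upward outliers (narrowband peaks) from an initial robust fit;
a joint peak + aperiodic model is deliberately out of scope.

## Trajectory statistics

Candidate models are polynomials of degree 1–5 with the animal as the LOOCV
unit. Selection uses the one-standard-error rule: the lowest degree whose
LOOCV MSE is within one standard error of the minimum. Strict minimum-MSE
selection (available as `rule="min"`) picks an overfit degree on ~20–25% of
truly linear cohorts at any cohort size — the familiar selection
inconsistency of cross-validation — which would defeat the linear/nonlinear
discrimination the trajectory analysis rests on.

The nadir bootstrap resamples animals with replacement within each age,
jitters ages uniformly over a 0.5-unit window, refits the chosen degree, and
records the age of the first interior extremum (smallest age where the
fitted derivative changes sign inside the observed range), binned to the
nearest observed age; mass for resamples with no interior extremum is
reported explicitly. The null resamples values across all ages — destroying
the age–value pairing while preserving the marginal distribution — so a
within/null mass ratio well above 1 at the mode certifies a genuine interior
extremum rather than a generic tendency of flexible fits to bend. The
default is 10,000 resamples; the validation experiments use 2,000, which
leaves the mode location and mass ratios unchanged at their reported
precision. In the vertex-recovery experiment the bootstrap runs at the
quadratic degree of the generating family after LOOCV confirms a nonlinear
fit, isolating localization accuracy from degree-selection variance.

The combinatorial maturation metric is, by default, the within-cohort mean of
(z(extent), −z(asymmetry), −z(power)) — maturation raises extent and lowers
asymmetry and power — and is invariant to per-feature affine rescaling; a
first-principal-component alternative is selectable and every output records
the rule id, since no canonical combination formula exists. The maturity
classifier is a coarse decision tree (≤ 4 splits) on spatial extent and ESR
with stratified 5-fold cross-validated accuracy and per-class marginal
feature histograms.

## Synthetic data: what it emulates, what it does not

The LFP generator superimposes Tukey-windowed oscillatory bursts (controlled
onset, duration, center frequency, amplitude, channel footprint) on 1/f^β
background noise (β = 1.5 default, spectral shaping of white noise), with
optional trace-alternant-like silencing of background blocks and optional
gamma carriers sharing the event envelope (amplitude-amplitude coupling
only, no phase–phase structure). Waveform asymmetry is second-harmonic
distortion `sin φ − a·cos 2φ`, which sharpens peaks and flattens troughs
monotonically for a ∈ [0, ~0.25]; beyond that the trough splits and the
ESR mapping folds back, so generator defaults stay within the monotone
range. (A pure phase-skew such as `sin(φ + a sin φ)` alters rise/fall times
but leaves peak/trough sharpness — and hence ESR — exactly 1, so it cannot
emulate the asymmetry the analysis measures.)

EMG is broadband noise above 300 Hz with piecewise-constant envelope (atonia
baseline, wake bouts at 6× RMS, twitches at 8× for < 1.5 s). Spike trains are
Poisson with a multiplicative in-event rate gain, optional von Mises phase
placement relative to the event carrier, a refractory interval, biphasic
0.6-ms transients injected at a stated multiple of the high-band floor, and
optional duplicate echoes on a paired channel within 2 ms. Cohorts draw
per-animal values from a polynomial mean trajectory plus Gaussian noise, with
the true interior extremum stored analytically.

None of this reproduces biophysics: no volume conduction or electrode
geometry beyond nominal positions, no state-dependent spectra, no
non-Poisson spiking beyond the imposed modulation, no artifacts other than
the constructions above. Passing the validation suite therefore certifies
the statistical machinery — detection, calibration, localization — under the
assumed signal model, not performance on any particular real recording.

## Validation study conditions

The experiments in `spindlekit.validation` use: 100 injected events
(0.3–2 s, 5× background RMS) at 1250 Hz for detector recovery; 60 s of pink
noise for PAR oracle equivalence; 100 events with skew 0–0.2 for ESR
monotonicity; 20 seeded runs of 40 events each (envelope share 0 or 0.8 at
50 Hz, 500 Hz sampling) for coupling calibration; 10 Poisson trains (5 Hz ×
400 s) for ACG coverage, 1000 uniform-phase draws (n = 100) for the Rayleigh
type-I rate, and a κ = 5 cohort of ~900 event spikes for concentration
recovery; 20 cohorts of 7 animals/age over ages 5–14 with a quadratic vertex
at 8.5 and noise 0.3× the trajectory range (2,000 bootstrap resamples) for
nadir recovery; 20 cubic and 20 linear cohorts for model selection; 10
two-minute EMG plans for state scoring; and a two-channel, two-minute
pipeline run executed twice for byte-identity. These sizes keep the full
suite and the acceptance script to a few minutes on one CPU while leaving
every pass/fail margin wide.

## Known limitations

EDF writing covers the minimal single-rate continuous case needed for
round-trip tests. The aperiodic fit is a masked robust line, not a joint
peak + aperiodic model. Human sleep staging is taken as given (clinical
annotation); only the rodent EMG path is scored in-package. The spatial
extent denominator uses all functional channels; subset denominators for
sparse clinical montages are a caller's choice. The comodulogram's
effective-sample-size correction is approximate (lag-windowed Bartlett sum)
and intentionally conservative at low frequencies.
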