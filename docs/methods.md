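# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic generators emulate, and the limits of what
the passing tests demonstrate.

## Signals and their common conditioning

Four signal families are compared on a common footing: acoustic feature
tracks, behavioral salience (percent of listeners attending), EEG band
energies, and per-layer network surprisal. Every continuous series is
conditioned identically before any correlation: resampled to 10 Hz
(polyphase), truncated to at most 120 s, first 2 s discarded (trial-onset
transients), then band-limited to [1/30, 1/6] Hz with order-4 Butterworth
high- and low-pass responses applied with zero phase. Zero phase matters
because lags are interpreted explicitly; a causal filter would smuggle its
group delay into every lag estimate.

The band limit is implemented spectrally: the series is linearly
detrended and its DFT multiplied by |H_hp(f)|²·|H_lp(f)|², the exact
magnitude response that forward–backward (filtfilt) application of the
order-4 filters realizes. A recursive filtfilt was evaluated and
rejected: the 1/30 Hz high-pass has warm-up transients spanning tens of
seconds, a large fraction of a 118 s record, and those edge-locked
transients dominated the narrow passband (planted-lag recovery degraded
to r ≈ 0.6 and stop-band attenuation to ~16% RMS). The spectral form has
no finite-length transients; the detrend removes the wrap-around step
that circular filtering would otherwise leak into the passband (the trend
lies below the high-pass band and would be removed regardless).

Two consequences are worth knowing. First, a 0.5 Hz probe sine (3× the
low-pass cutoff) is attenuated to ~0.4% RMS, consistent with the
closed-form |H|² = 1/(1+3⁸) plus residual spectral leakage. Second,
conditioning is only approximately idempotent: re-applying the band gain
to broadband input shrinks RMS by the closed-form factor
1 − √(∫g⁴/∫g²) ≈ 9.1%, because much of the energy that survives one pass
sits on the filter skirts. For content near the passband center the
change is under 5%. Both facts are asserted in tests against their
closed forms.

## Acoustic front-end

Audio is resampled internally to 16 kHz so the 25 ms window and 10 ms hop
of the mel front-end are exact sample counts (400/160). Frames are
centered with reflect padding and the frame count is ⌊N/hop⌋, a
convention chosen so a 960 ms patch yields exactly 96 frames; with 64
triangular mel bands on 125–7500 Hz and log compression (additive floor
10⁻⁶, so digital silence maps to a constant) this produces the 96 × 64
network input.

The ten feature tracks are computed on 200 ms frames hopped by 100 ms
(10 Hz, matching the conditioned rate): loudness = frame RMS in dB;
brightness/bandwidth = spectral centroid and spread; flatness =
geometric/arithmetic mean ratio of the power spectrum with a
peak-relative floor (keeping the measure scale invariant); irregularity =
normalized squared successive-bin differences; pitch and harmonicity =
location and normalized height of the autocorrelation peak in 50–2000 Hz;
rate and scale = energy centroids of the temporal and spectral modulation
spectra of the log-mel block under the frame. These are standard
definitions matching the quantities' names; exact equivalence with any
particular earlier toolbox is not claimed.

Roughness is the average magnitude of the amplitude-modulation spectrum
between 30 and 150 Hz, normalized by frame RMS. The envelope is the
magnitude of the analytic (Hilbert) signal, mean-removed before the
transform; the normalization makes the measure invariant to overall
level, and a silent frame is defined to have roughness 0. The envelope
choice is a repo decision (the modulation band is the defining part); a
brute-force DFT oracle pins the implementation to 1%.

## Network and surprisal

The CNN is the published architecture, dimensions locked by tests:
96×64 → conv3×3(64) → pool → conv(128) → pool (**Pool2**, 49,152) →
conv(256) → pool (**Pool3**, 24,576) → conv(512) (**Conv4**, 49,152) →
pool (**Pool4**, 12,288) → **FC1** (4,096) → **Embed** (128) → prediction
(4,923). ReLU follows every convolution and fully connected layer
(standard for this family); convolutions are same-padded, pooling is
non-overlapping 2×2 — the printed layer sizes force these conventions.
One published number does not survive arithmetic: the input patch is
96 × 64 = 6,144 values, not the 16,384 printed alongside it; the package
follows the dimensions.

Weights default to seeded He-scaled Gaussians with zero biases; training
is out of scope and the entire downstream analysis operates on the
activations of whatever network is supplied (an `.npz` with one named
array per layer, shapes validated, drop-in replaces them). Activation
time series slide the 960 ms patch in 0.1 s hops over the scene's mel
spectrogram, computed once; each frame is stamped with the window END
time so surprisal at t uses only audio up to t.

Surprisal is the Euclidean distance between the current flattened
activation vector and the element-wise mean of the strictly preceding
4 s. Frames with under 1 s of history are undefined (NaN); frames with
1–4 s use the available mean. The undefined head falls inside the 2 s
the conditioning step discards; `SurprisalSeries.filled()` back-fills it
for fixed-length plumbing. No dimensionality normalization is applied —
cross-layer comparisons go through correlations, which are scale-free
(surprisal itself is exactly scale-equivariant, a tested property).

## Behavioral model and event detection

The behavioral construct is the percentage of listeners attending to a
scene at 10 Hz. The generator simulates each listener as a two-state
(attend/ignore) Markov chain — the minimal process producing event-locked
derivative peaks in a percentage-attending curve: baseline switching
hazard 0.05/s in both directions, and for 2 s windows starting one motor
delay (1.4 s) after each planted event the switch-to-attend probability
is multiplied by (1 + gain), gain 20 by default. Twenty subjects is the
default cohort.

Detection mirrors the construct: derivative of the curve, smoothed by the
same three-pass 5-sample moving average used for feature slopes; peaks
below 0.5 SD of the derivative are noise-floored; peaks closer than 1 s
merge into the larger (smoothing ripple would otherwise split one rise);
strength = z(slope height) + z(max attending in the following 4 s) —
equal weights on z-scored components, since the combination weights are
otherwise unspecified; the top 50% by strength is kept (ceil on ties of
count). Event categories come from the nearest ground-truth annotation.

Recovery benchmark: on sparse scenes a planted event counts as recovered
when a detected event lies within ±1 s of onset + motor delay; measured
offsets center ~0.4 s after that point. Dense scenes are excluded from
the recovery metric by design: at 3× the sparse event rate the boost
windows overlap and the attending percentage saturates, merging
neighboring events — the same regime in which behavioral salience is
genuinely hard to attribute. That exclusion is a documented property of
the benchmark, not of the detector.

## EEG path

Raw multichannel signals are assumed already cleaned of line noise and
ocular artifacts upstream (those removal algorithms are out of scope);
the package demeans, detrends, resamples to 256 Hz, and re-references to
the common average. Band energy is the mean power over the band's bins
of a Hann-tapered FFT in 1 s windows advanced by 100 ms — power, not
amplitude, averaged across bins (a flagged choice) — then z-scored per
channel and band over the scene. Window starts live on the 0.1 s time
grid with per-window rounding to samples, so the output rate is exactly
10 Hz even though 0.1 s is 25.6 samples at 256 Hz (120 s gives 1,191
windows). Electrode groups (e.g. 21 frontal electrodes near Fz, 23
central near Cz) are free-form labels per channel, never a hard-coded cap
layout. The 1 s analysis window smears timing by up to ~half a window,
which bounds lag recovery through the raw spectral path to about ±0.5 s;
the 10 Hz band-energy surrogate generator (which plants lags directly)
recovers lags to ±0.1 s and is the instrument for precise lag tests.

## Layer-level statistics

Layer trends are ordinary least squares of a metric on layer index
(0…5), pooling all replicates (scenes, events or time points — the
pooled-replicate accounting is this package's convention), with t, p and
99% CI on the slope; exact fits short-circuit to the analytic limits
(t = 0, p = 1 for a zero slope with zero residual). Cumulative variance
explained runs one simple regression per layer, shallow to deep, each on
the previous residual, reporting 1 − var(residual)/var(original); it is
non-decreasing and bounded by 1 by construction. The chance baseline
replaces every layer after the first with seeded N(0,1) series; a random
regressor explains 1/(n−1) of the remaining variance in expectation, and
the tests hold the measured mean increment to that within two standard
errors. Group contrasts (dense vs sparse) compare per-layer mean
differences between the three early (Pool2/Pool3/Conv4) and three deep
(Pool4/FC1/Embed) layers with a two-sample t test (df = 4). Per-category
analyses are the same cumulative-variance operation applied to
concatenated ±3 s event windows (salience delayed 1.4 s), filtered by
category label.

For event-windowed correlations, significance uses a circular-shift null:
the salience series is rotated by a random offset and the event windows
recomputed. Band-limited series are smooth, so window correlations are
large in magnitude everywhere; shifting preserves that marginal structure
while destroying time-locking, which is the effect under test. (A
redraw-the-event-times null was evaluated and is badly anti-conservative
here for exactly that reason.)

## Event prediction

Bins of 2 s advanced by 0.5 s (a 118 s series gives 233 bins); a bin is
positive iff an event onset lies in its closed span. Predictors are
per-bin means of acoustic-feature slopes (derivative then three passes of
a 5-sample moving average at 10 Hz — the window length is exposed, since
the right amount of smoothing depends on event density) and of per-layer
surprisal, each optionally time-aligned by its best ±3 s lag against
salience before binning. Classification is linear discriminant analysis
(class-conditional Gaussians, pooled covariance; the SVD solver tolerates
collinear predictors) under seeded stratified five-fold cross-validation;
held-out scores are pooled into a single ROC and AUC.

## What the synthetic studies do and do not show

The generators emulate the statistical skeleton of a natural-scene
salience study: scenes as 1/f background plus parametric event tokens
(harmonic complexes with pitch contours for speech, note sequences,
vibrato glides, band-limited swells, impulsive bursts) at sparse
(0.05 events/s) or dense (0.20/s, ≥3×) rates; listeners as event-coupled
Markov chains; band energies as lag-shifted weighted copies of a driver
plus noise, or raw carriers amplitude-modulated by it. Sizes used in the
shipped studies — 6 scenes, 120 s, 20 subjects, 20 trend replications —
are the package's standard benchmark conditions.

Passing tests therefore demonstrate that the machinery recovers what was
planted: event times through the behavioral chain, lags through the
correlation chain, orthogonal variance decompositions, declining layer
profiles, and added surprisal information in prediction (acoustic
features respond to ~70% of events, surprisal surrogates to all, so the
combined classifier must win if information flows). They do not
demonstrate anything about real recordings: natural scenes have semantic
structure, listeners are not two-state chains, EEG is not a shifted
driver, and a randomly initialized network is not a trained one. The
published study-specific statistics (AUCs, trend slopes, event counts
per category) depend on the original data and are deliberately not
targets.

## Numerical conventions

Positive lag always means the second signal follows the first. Percent
scales are 0–100. All randomness flows through `numpy.random.default_rng`
with explicit seeds; generators are byte-reproducible under a fixed seed.
Degenerate inputs have defined behavior throughout: silence has roughness
0, flat curves yield no events, zero-variance overlaps flag the
correlation as undefined rather than raising, and zero-variance targets
are rejected where a variance ratio would be meaningless.
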