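# Methods

`muadecode` asks a simple question with a simulation: if you know the
spike waveforms of the neuron types under an electrode, can band-limited
power (BLP) in the multiunit-activity (MUA) range substitute for spike
sorting — detecting spikes, naming their cell type, and tracking each
population's moment-to-moment firing rate?  The model system is the
mouse dorsal striatum, whose two dominant extracellular signatures are
medium spiny neurons (MSNs: broad spikes, FWHM > 200 µs, low rates)
and fast-spiking interneurons (FSIs: narrow spikes, FWHM < 200 µs,
high rates).

## Synthetic waveforms

Templates are 2 ms (40 samples at 20 kHz), biphasic, and built from two
parts:

* a positive lobe `exp(-|t/τ|^p)` with an asymmetric time constant
  (rise τ is one third of the fall τ), parameterised directly by FWHM;
* a slower negative (after-wave) Gaussian lobe.  MSN after-waves have
  amplitude ratio 0.35 and width ratio 4× the positive lobe; FSI
  after-waves 0.5 and 2×.

The shape exponent `p` is the one genuinely free parameter and it
controls the spectral tail: `p = 1` is a cusp (power falls off as
f⁻⁴, like the fast voltage transients of real narrow spikes) and
`p = 2` is Gaussian-smooth (super-exponential falloff).  FSIs use
`p = 1`.  MSNs use `p = 1.6`, chosen so that for the default 95:5
population the *aggregate* spectral contribution crosses from
MSN-dominated to FSI-dominated near 3 kHz — the transition band
striatal recordings place between 3 and 6 kHz — which simultaneously
leaves a deliberate MSN "leak" into the 8–10 kHz band.  That leak is a
feature, not an artifact: it produces the reported confusion structure
in which high MUA tracks *both* populations and FSI direction decoding
stays only modestly above chance whenever MSNs co-modulate.  A
Gaussian MSN lobe (p = 2) removes the leak and makes FSI decoding
unrealistically easy; a cusped MSN lobe (p ≤ 1.3) hands the high band
to the MSNs and makes FSI tracking impossible.  Both edges contradict
the observed decoding structure, so p = 1.6 was fixed once and not
revisited.

Both template edges are cosine-tapered (first/last 10 % of the
snippet): an amplitude step at the insertion boundary would inject
spurious f⁻² broadband power at every spike time.

The measured FWHM (linear interpolation at half maximum) of the
composite lobe runs slightly narrow of the analytic lobe width, so
construction solves for the internal width by fixed point; round-trip
accuracy is within one sample over the full 100–600 µs range.

Default libraries: 40 MSN templates (FWHM uniform 250–450 µs,
peak-peak 80–160) and 25 FSI templates (100–190 µs, 50–110), echoing
the recorded-unit counts (43/25) and the broad/large vs narrow/small
split.

## Populations and spike trains

A population draw fixes exact type counts (default 20,000 cells,
95 % MSN), per-cell mean rates from zero-truncated normals
(MSN 2.4 ± 3.6 Hz, FSI 16.1 ± 10.2 Hz; negatives re-drawn, so the
realised MSN mean is ≈ 3.9 Hz — the truncation bias is real and
intended), and a uniformly random template per cell.

The drive schedule is five 10-s conditions: rest, MSN-only, FSI-only,
anti-phase, in-phase.  Within a modulated window each *responsive*
cell's rate is `mean_rate · max(0, 1 + d·sin(2π·0.5·(t−t₀)))`; the
sine restarts at phase 0 per window and is negated for FSIs in the
anti-phase window.  Modulation therefore both drives and silences
cells.  The depth `d` is calibrated per type by bisection (0.5 Hz
tolerance, 5 seeds) so that at 100 % responsiveness the maximum
per-neuron population rate in 10-ms bins hits 78.2 Hz (MSN) and
141.5 Hz (FSI); typical calibrated depths are ≈ 19 (MSN) and ≈ 7
(FSI).  Calibration simulates binned aggregate Poisson counts
directly, which is distribution-identical to binning the thinned
trains and essentially free.

Spike trains are sampled by thinning one aggregate homogeneous
Poisson process per (type, window) and assigning accepted events to
cells with probability proportional to mean rate.  This is exactly
equivalent to independent per-cell inhomogeneous Poisson processes
(verified by a time-rescaling Kolmogorov–Smirnov test) and is what
makes 20,000-cell, 50-s simulations take seconds.  Rendering groups
spikes by template and convolves per-template impulse trains, aligned
to the positive peak at the nearest sample.

## Noise

Non-neuronal noise is parametric: a 60 Hz line plus broadband
Gaussian, with total noise RMS = 0.5 × the RMS of the *rest-window*
neural signal and 99.8 % of the noise power in the line.  Two
considerations fix these defaults.  First, the noise floor is a
property of the rig, so it is referenced to spontaneous activity;
scaling against the whole trace would let evoked bursts inflate it.
Second, the noise this model emulates was dominated by line hum and
did not materially affect any accuracy measurement — which requires
the broadband remainder to stay below in-band spike power even in the
weak 8–10 kHz band.  With these defaults, >300 Hz BLP changes by
< 5 % when noise is added (tested), while the wideband trace is
visibly 60 Hz-contaminated.

## Spectral pipeline

Snippet spectra: 20-ms segments zero-padded to 4096 points, 2048
positive-frequency bins to 10 kHz, the 4500–5000 Hz environmental
band excised (NaN) *before* normalising the remainder to unit area.
BLP: 5-pole Butterworth, applied forward and backward
(`sosfiltfilt`, reflective padding of ~3 low-edge periods), squared
pointwise; a band reaching Nyquist degenerates to a high-pass.
Zero-phase filtering doubles the effective order; the design order is
what is specified, so that is what is doubled.  Band grid: theta 4–8,
alpha 8–12, beta 12–25, gamma 30–100 Hz, then contiguous 100-Hz bands
to 10 kHz.

Correlation significance is computed through
`t = r·sqrt(n−2)/sqrt(1−r²)` with n−2 degrees of freedom.

## Detection and single-spike classification

Detection z-scores the BLP of a band over the whole trace (sample SD,
ddof = 1 — the convention all z-scores in the package share), and
calls a spike detected when the mean z within ±1 ms exceeds 2.  Every
sample outside all spike windows with z ≤ threshold is a true
negative; specificity is computed per sample (a binned variant was
considered and rejected as the default for being resolution-dependent).

Putative spikes for classification are local maxima of z-scored
> 300 Hz BLP above 1 SD, at least 25 ms apart (merged to the larger
peak); ±25 ms snippets are transformed and area-normalised, and the
integrated power in 500–600 Hz and 3000–3500 Hz forms the feature
pair.  A linear soft-margin SVM (C = 1, features standardised on the
training set) separates the types.  Evaluation is per *cell*: 25 % of
cells per class train the model, held-out cells are scored per
snippet with missed spikes counted as errors, per-cell accuracies are
averaged within class.  Per-snippet pooled accuracy is also reported;
per-cell is primary.

## Population decoding

All decoders compare against rest statistics (mean, SD over 0–10 s of
the 10-ms-binned quantity):

* ground truth per bin: each type's rate is up/down/none by the
  ±2 SD rule;
* 8-way pattern: low-MUA (0.3–2 kHz) z → MSN state, high-MUA
  (8–10 kHz) z → FSI state, same ±2 SD rule; bins whose true pattern
  deviates in at least one type are scored on the exact joint pattern
  (chance 1/8);
* 2-way: bins where the scored type's true state deviates are scored
  on that type's predicted state matching the true direction (a
  "none" prediction is an error; chance 1/2).  The alternative
  sign-of-deviation rule is available (`direction_prediction`) but
  saturates near 99 % for MSNs and overshoots every reported value;
* continuous: `pred = rest_rate_mean + z_BLP · rest_rate_SD`, with
  z relative to rest BLP statistics.  Reported correlations are
  per-10-ms-bin over the four modulation windows; a 30-rate-bin
  scatter summary (mean ± SD predicted per actual-rate bin) is also
  produced for display.  Percent error is `100·|pred−actual|/actual`
  per bin, zero-rate bins excluded and counted.

Low MUA predicts MSNs and high MUA predicts FSIs throughout; this
band-to-type mapping is the only one consistent with the spectral
signatures above.

## What the synthetic data does and does not emulate

The generator reproduces the rate statistics, waveform width/amplitude
statistics, spectral signatures, drive schedule and noise character of
the study conditions.  It does **not** vary electrode–neuron distance
(no amplitude/filter heterogeneity within a cell), does not model
synchrony or synaptic potentials, and inserts each cell's *average*
waveform.  Passing tests therefore show the decoding pipeline behaves
correctly on idealised MUA whose composition is exactly known; they do
not show the decoder would reach the same accuracies on in-vivo
recordings, where all reported accuracies would be expected to drop.
Two reported quantities are systematically cleaner here than in the
original study for exactly this reason: 2-way MSN direction accuracy
(our low band is less contaminated, so accuracy saturates ~10 points
high at full responsiveness) and, at 20 % responsiveness, the ±2 SD
state rule cannot see rate *decreases* at all (a 20 %-responsive
population cannot pull its aggregate BLP two rest-SDs down), which
halves the reported 2-way accuracy there.  Both are discussed in the
test suite rather than hidden.

## Numerical choices

* Spike insertion at `round(t·fs)`, 0-based; bins half-open
  `[t, t+10 ms)`.
* Sample SD (ddof = 1) everywhere a z-score or rest SD appears.
* Bisection brackets depth in [0, 200] and fails loudly if the target
  peak is unreachable.
* Degenerate inputs raise typed errors (`ShapeUndefinedError`,
  `SpectralError`, `DecodeError`, ...) rather than returning NaN,
  except where a missing value is the documented answer (sensitivity
  of an empty spike train, r of a constant window).
* All randomness descends from one root seed through named
  substreams (library, population, calibration, trains, noise,
  split); sub-seeds stay below 2³¹.

## Problem sizes

Default test and example configurations use the full 20,000-cell,
50-s, 20 kHz simulation (one such run simulates, renders and decodes
in well under a minute); sweeps use 5 seeds per responsive fraction
(2–3 in the test suite).  Unit tests use smaller populations
(1–2,000 cells) where the property under test does not depend on
population size.
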