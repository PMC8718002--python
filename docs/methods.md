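# Methods

`floralecho` implements an end-to-end, simulation-backed version of an
echo-acoustic flower study: ultrasonic impulse-response (IR) measurement by
maximum-length-sequence (MLS) deconvolution, calibrated spectral target
strength (TS), bell-flower morphometrics, the associated statistics, and
echo-spectrogram species classification with a multi-input convolutional
network. This note records the models, the parameters that matter, and the
design decisions taken where several choices were defensible.

## Measurement model

A target is ensonified with a continuously repeated MLS (order 14 by
default: 16 383 samples, 32.77 ms at 500 kHz — "33 ms" to instrument
precision). Because the circular autocorrelation of a maximal sequence is
`L` at lag 0 and `-1` elsewhere, circular cross-correlation of the
steady-state recording with the sequence recovers the IR. A 2 s recording
holds 61 whole periods; the first is the transient build-up, leaving 60
identical steady-state periods of which 50 are averaged (periods 2–51),
raising SNR by `10 log10(50) ≈ 17 dB`. The correlation is normalized by the
sequence length; the residual `(L+1)/L` amplitude factor and the `-1/L`
off-peak floor are below 0.001 dB and are ignored.

The echo is cut from the averaged IR with a rectangular 1024-sample window
placed 128 samples before the largest-magnitude sample found after a guard
interval (default 0.8 ms) that skips direct loudspeaker–microphone
crosstalk; with the 20 cm measurement range the target echo arrives at
~1.17 ms. A peak below 5× a robust noise-SD estimate (median/0.6745) is
reported as "no echo"; for pure Gaussian noise the analytic false-positive
probability over 16 383 samples is ≈0.9 %.

TS is the dB ratio of the windowed echo's power spectral density to that of
a reference plate processed through the identical chain, which cancels any
common emitter/receiver coloration; the result is referenced to the plate at
10 cm and no additional spreading-loss normalization is applied. Analysis
bands are the broad 40–160 kHz band and four narrow bands at 45, 68, 102
and 153 kHz with ±20 % edges; band membership is by bin center in the closed
interval (the 488 Hz bin spacing makes the dialect nearly irrelevant). All
averaging of dB quantities — across bins in a band, across the 101 angles of
a scan plane, and across the azimuth/elevation planes — is done on linear
power ("after delog") and converted back to dB at the end. `process_scan`
computes the band average directly in the linear domain; this is
algebraically identical to calibrating in dB and delogging again (the round
trip cancels), and the equivalence is asserted to ~1e-9 dB in the tests.

## Synthetic-data generator

No recordings ship with the package, so a generator produces data with the
statistical structure the analysis assumes. What it emulates, and what it
does not, determines what green tests mean: they validate the *pipeline*
(signal chain, statistics, classifier mechanics and their calibrated
recovery of known ground truth), not any claim about real flowers.

**Catalog.** Six families, each with one bat-pollinated and one insect/
bird-pollinated species (codes follow the field study's species list).
Family base sizes are log-spaced (scale 0.5–2.0 around a template flower
with 28 mm corolla, 22 mm depth, 24 mm outer diameter), so surface areas
span roughly 1.5 orders of magnitude (~250–8000 mm²) and the TS–area
regression is identifiable; each species gets ±16 % size and ±10 % per-
feature shape jitter per seed, making syndrome and size uncorrelated in
expectation.

**Flowers.** Every feature is drawn as `mean·(1 + cV·z)` with `z` standard
normal, rejected and redrawn (≤100 times) if non-positive. The calibrated
relative variability is cV = 0.08 for bat species and 0.16 for others, with
±20 % per-species jitter so species differ within a syndrome. At n = 14 the
sample-SD bias (`c4(14) ≈ 0.981`) puts empirical group means near
0.0785/0.157.

**Impulse responses.** Each IR is a two-path reflector: a rim reflection at
the window onset and an interior-wall reflection delayed by the round trip
over the projected depth, `2·depth·cos(θ)/c`. Superposition of the two paths
produces spectral notches spaced `c/(2·depth·cos θ)`; larger (deeper) bells
therefore show more interference notches in a fixed band, and the notch
positions shift with ensonification angle, giving the "spotted" directional
spectrum. The interior amplitude falls off in a Gaussian lobe (35° default)
around the opening and a smooth ±6 dB directivity ripple is applied. At
depth → 0 the IR degenerates to a single flat reflector. This is the
simplest mechanism reproducing the qualitative size-vs-interference
observation; it ignores petal texture, material impedance, multiple
scattering and everything else a real flower does.

**TS calibration.** Flower-level broadband TS follows
`TS = a·ln(area) + b ± offset/2 + ε`, with the fitted field coefficients
`a = 3.488` dB per ln(mm²), `b = −32.422` dB as defaults, a syndrome
contrast of 3 dB (bat above other), and `ε ~ N(0, 0.6 dB)`. The offset is
applied as a centered contrast so the pooled regression converges to
`(a, b)` while the bat−other residual separation equals the configured
offset. The residual SD and the size span were chosen together so the
simulated regression has R² ≈ 0.8 while flower-to-flower TS noise does not
swamp the morphology-driven acoustic variability (which underlies the
acoustic-cV-tracks-morphological-cV property). Calibration is enforced by
measurement: the raw IRs are passed through the actual processing chain and
rescaled by a frequency-flat gain until the recovered broadband overall TS
equals the target, so generator and measurement cannot drift apart.

**Call.** A 1.5 ms hyperbolic downward FM sweep (fundamental 80→42 kHz)
with a second harmonic at half amplitude, Hann-tapered — a glossophagine-
like call shape with documented, configurable constants; >99 % of its energy
lies above 40 kHz. It is high-passed at 5 kHz before echo synthesis.

**Determinism.** All draws flow from explicit seeds through
`numpy.random.Generator`; per-flower streams are derived from
`(seed, crc32(flower_id))`, so any flower's scans can be regenerated in
isolation, bit-identically.

The generator's count of echoes per flower is `2 × n_angles` (202 at the
default grid); no attempt is made to reproduce any particular historical
total echo count.

## Statistics

* OLS of band TS on `ln(area)` (statsmodels), reporting slope, intercept,
  R², `F(1, n−2)` and residuals.
* Welch's unequal-variance t-test on residuals grouped by syndrome
  (fractional degrees of freedom), two-sided.
* Coefficients of variation use the sample SD (n−1). Acoustic cV of band TS
  is computed on delogged (linear-power) values: the dB values here are
  negative, which would flip the sign of σ/μ.
* Mixed-model stage: likelihood-ratio comparison of nested linear mixed
  models with a random family intercept, both refit by maximum likelihood
  (REML likelihoods are not comparable across fixed-effect structures). The
  LR χ² is asymptotic; at n = 168 with 6 families its null type-I error is
  close to, but slightly above, the nominal 5 % (checked by simulation in
  the tests). Boundary effects for variance components do not arise because
  only fixed effects are tested. Non-convergence is reported, not swallowed.
  No multiple-testing correction is applied.

## Classifier

Echoes are synthesized on demand (call ∗ IR, fixed length, default 2048
samples), turned into magnitude spectrograms (Hann 256, hop 26 ≈ 90 %
overlap, dB with −80 dB floor, min–max normalized per spectrogram; rendered
spectrograms are memoized, which is sound because the mapping is
deterministic). Chunks of k ∈ {1, 3, 5, 7, 10} echoes from one flower are
the classification unit; *random* chunks shuffle a flower's pooled
azimuth+elevation echoes and partition them (remainder dropped), *interval*
chunks take every n-th echo (n ∈ 2..8) in one plane's angular order with no
wrap-around, count-matched to the random scheme for fair comparison.
Splits assign whole flowers per species to train/validation/test (default
8/2/2 of 14; leftovers unused unless requested), so no flower's echoes cross
subsets.

The network is implemented in numpy: each echo passes a shared-weight
branch (conv 16×3×3 stride 1 → ReLU → max-pool 3×3 stride 2), the k branch
outputs are concatenated along channels, a trunk (conv 32×3×3 → ReLU →
pool) feeds three dense layers (256, 128, n_classes) and a softmax. Valid
padding, He initialization, float32 parameters, cross-entropy loss, Adam
(default learning rate 1e-4, batch 16 — the small desk-scale experiments in
the tests use 1e-3 to converge within their epoch budget), early stopping on
validation loss with patience 8 (best weights restored). Backpropagation is
exact (checked against finite differences to ~1e-9 in float64). Dense
widths, activation, dB floor and normalization are package choices and are
documented defaults. Evaluation reports the confusion matrix (true classes
in rows), overall accuracy, and per-syndrome accuracies with exact 95 %
Clopper–Pearson intervals.

## Problem sizes used by the shipped experiments

The replicated experiments run at the study's native size (12 species × 14
flowers, two 101-angle planes): 200 replicates for the regression recovery
and 50 seeds for the cV group means. The classifier experiments are
desk-scaled — 3 well-separated species (size scales 0.5/1.2/2.8, cV 0.03),
6 flowers each (4/1/1 split), 15 angles per plane, 1280-sample echoes,
≤30 epochs — sizes at which the qualitative properties (≥90 % accuracy at
k = 3, accuracy non-decreasing in k, random ≥ interval sampling, bat species
easier early in training) are stable and quick to demonstrate. Statistical
properties are asserted with confidence-interval-overlap allowances or
averaged over seeds, as appropriate for stochastic quantities.

## Known limitations

* The two-path IR model captures interference combs and directivity lobes
  but no higher-order structure; directional spectra of real flowers are far
  richer.
* TS noise is i.i.d. per flower; systematic frequency-dependent deviations
  (e.g. the high-band cluster some species show in the field data) are not
  modelled.
* The mixed-model χ² and the classifier accuracies of the original field
  recordings are not reproducible from simulation and are not targets here.
* WAV I/O is 32-bit float via scipy; recordings at unexpected sample rates
  are refused rather than resampled.
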