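# Methods

`singtrack` implements an encoding analysis of infant EEG recorded during
live infant-directed singing, together with a synthetic-dyad generator that
provides ground truth for every stage. This note documents the models, the
estimator choices, the generator's assumptions, and the numerical details a
user would need to trust or extend the results.

## The encoding model

Neural tracking is quantified with a temporal response function (TRF): a
linear kernel `w(c, τ)` mapping the sound's broadband amplitude envelope
`s(t)` to the EEG of channel `c`,

    ŷ_c(t) = Σ_τ w(c, τ) · s(t − τ) + b_c ,     τ ∈ [−100, +500] ms,

sampled at the common 500 Hz rate (2 ms lag step, 301 lags). Weights solve
the ridge system `(XᵀX + λ·m·I)⁻¹XᵀY` per channel, where `X` is the lag
matrix with columns centered and variance-normalized by training statistics
and `m` is the mean diagonal of the normalized `XᵀX`. Scaling the penalty by
`m` makes the λ grid comparable across subjects whose envelopes differ in
variance.

**λ selection.** λ is chosen per subject and condition from the grid
10⁻⁷…10⁷ (integer exponents, 15 values) by 5-fold cross-validation over
contiguous folds within the training split (the leading 80% of retained
epochs); the criterion is the mean held-out Pearson correlation across folds
and channels, ties resolve to the smaller λ, and the final model is refit on
the full training split. The held-out test set is the trailing contiguous
20%; contiguity limits autocorrelation leakage between train and test.
Predictive accuracy is the per-channel Pearson r between predicted and
observed test EEG, Fisher-z transformed (`z = arctanh r`) before any
group-level modeling. Degenerate records (zero-variance or |r| ≥ 1 − 1e−12)
are flagged and excluded from aggregation.

**Boundary rows.** Epochs are 1 s long and lag windows never cross an epoch
boundary; out-of-range design entries are zero-padded. Rows whose lag window
is incomplete would present the model with regressors the recorded EEG never
saw, which we found biases the weights substantially (kernel-recovery
correlation 0.38 → 0.99 at snr 4 after excluding them), so by default only
boundary-free rows enter the normal equations (`fit_rows="valid"`, the
analogue of mTRF-Toolbox's `zeropad=false`); prediction and scoring still
use full epochs. `fit_rows="all"` restores the naive behaviour.

## Permutation inference

**Shifted-pairing null.** The concatenated test EEG is time-reversed and
circularly rotated by an independent uniform shift of at least 1 s for each
of 400 permutations; per-channel correlations with the unchanged prediction
form the null. Reversal plus rotation destroys the true temporal alignment
while preserving the autocorrelation spectrum. Because reversal is a fixed
transform, reversing once or per permutation is equivalent; both spellings
are accepted. The 1 s minimum shift comfortably exceeds the autocorrelation
scale of 1–10 Hz band-passed EEG.

**Cluster-based test.** Group TRF weights are tested against zero with
element-wise one-sample t statistics, a two-sided cluster-forming threshold
at p < .05, clusters grown along lag adjacency and an electrode neighbour
graph, cluster mass = summed t, and a max-mass null from 1000 random sign
flips of subjects (appropriate for a one-sample test). Clusters spanning
fewer than two distinct electrodes are discarded, mirroring the published
constraint. Electrode adjacency comes from template 10–20 positions with the
smallest distance threshold that gives every electrode at least 3 neighbours
while keeping the graph connected (median degree lands in 3–6).

## Audio features

The envelope pipeline decomposes audio into 128 bands of uniform width on a
log-frequency scale (centers 0.1–4 kHz), computed as a triangular log-spaced
filterbank on short-time magnitudes (2048-sample Hann window, 100 Hz frame
rate) — the fast equivalent of rectifying narrowband-filtered signals. Band
envelopes are low-pass smoothed at 30 Hz (retaining syllabic/beat-rate
fluctuations, discarding the carrier), summed, and resampled to 500 Hz,
length-locked to the audio time base.

Descriptors: frame RMS (50 ms frames, 50% overlap); frame-wise f0 by
normalized autocorrelation with parabolic interpolation over voiced frames
(voicing = ACF peak ≥ 0.5 and frame RMS above a quarter of the 90th
percentile); tempo and pulse clarity from the onset-detection curve (the
half-wave-rectified first difference of the broadband envelope). Variability
(SD) descriptors use 5-s windows with 50% overlap.

**Tempo peak choice.** The beat lag maximizes

    acf(L) + acf(2L)/2 − acf(L/2)/2 − acf(L/3)/3

over the 55–210 BPM search range (ties → slower tempo), followed by light
Gaussian smoothing and parabolic refinement. The naive global ACF maximum is
not reliable here: with independent onset jitter the expected ACF height is
identical at the beat lag and at its integer multiples, so the global
maximum halves or thirds the tempo essentially at random. The fractional-lag
penalties betray subharmonic candidates (their half/third lag carries high
autocorrelation), and the double-lag bonus adds beat-period evidence at
twice the lag resolution. Pulse clarity remains the raw ACF height at the
chosen lag normalized by lag 0 — on normalized-autocorrelation grounds it is
near 1 for metronomic trains and near 0 for flat envelopes; published
MIR-toolbox values are not comparable because that configuration is
unspecified, so clarity is validated on synthetic signals only.

## EEG cleaning

The chain and its defaults: zero-phase FIR band-pass 0.3–100 Hz (−6 dB at
0.15/100.15 Hz, transition 0.3 Hz, ~5500 taps applied by FFT convolution
with reflection padding); line-noise suppression at 50/100 Hz by clamping
FFT-bin magnitudes within ±0.6 Hz of the target to twice the flanking noise
floor (phases kept — line-free signals change by < 2% RMS, neighbours beyond
±2 Hz are untouched); bad-channel detection by z-scoring the mean log power
1–100 Hz across channels (|z| > 3, two passes, union; threshold and passes
config-exposed — note that the mean/SD statistic masks multiple simultaneous
outliers, so large flagged sets require iterative peeling); wavelet
artifact removal (coif4, depth 9 so the lowest level sits near 0.5 Hz, hard
level-dependent universal threshold σ√(2 ln N) with σ = MAD/0.6745; the
reconstruction of supra-threshold coefficients is subtracted); spherical-
spline interpolation of bad channels (MNE's implementation, template
positions); average reference over the 29-label scalp set; segmentation into
non-overlapping 1-s epochs with rejection of any epoch whose 200-ms sliding
window (step 1 sample) exceeds 100 μV SD on any electrode; subjects with
fewer than 90 retained epochs are flagged excluded. A final 1–10 Hz FIR
(501 taps, reflection padding) is applied per epoch, after epoching by
default (config-exposed, the published order being ambiguous). Every step
appends its parameters to a log that is serialized with the outputs.

Note the windowed-SD arithmetic: a square pulse of amplitude A can raise the
within-window SD to at most A/2, so a 150 μV transient alone does not trip
the 100 μV rule; the guarantee that ≥150 μV transients never reach the
encoder comes from the chain (wavelet thresholding attenuates them by ≥80%,
and anything surviving above threshold is caught by epoch rejection), which
is what the end-to-end test asserts.

## Group-level models

Fisher-z accuracies enter a linear mixed model `z ~ song type × data type
(× channel)` with per-dyad random intercepts and song-/data-type slopes
(ML; random structure falls back to intercept-only on non-convergence, and
a boundary fit with finite likelihood is accepted with a note). Term χ²
values are likelihood-ratio tests of ML fits: interactions against the
additive model, main effects by dropping the term from the additive model.
Post-hoc cell means and contrasts are linear combinations of fixed effects
marginalized over the remaining factors, with Tukey-style adjustment via the
studentized range (family = 4 cell means). Acoustic-feature models add
song type × feature interactions (features z-scored within the fit, one
model for means and one for SDs) and report per-condition simple slopes
("trends") with 95% CIs; robustness is judged by whether a CI excludes 0.
Channel enters as a fixed factor as printed; a channel-averaged variant
exists for simulation work.

Movement proportions are fitted with a beta-family GLMM (logit link):
a per-dyad Gaussian random intercept is integrated out by 20-node
Gauss–Hermite quadrature and all parameters (fixed effects, log precision
φ, log random-intercept SD) are estimated by ML with L-BFGS; standard
errors come from the central-difference Hessian. On one reference dataset
the estimates, SEs, φ, and random-effect SD agree with R's glmmTMB to three
decimals. Exact 0/1 proportions are pulled inside the interval by
(y·(n−1)+0.5)/n and noted. Vocabulary models add the standardized 20-month
expressive count as fixed and interaction effects on either tracking
(linear mixed model) or movement (beta GLMM); dyads with missing vocabulary
are dropped and counted, and fewer than five complete dyads refuses to fit.
Multiple comparisons use Benjamini–Hochberg q-values. Estimation defaults:
ML (not REML) so the LRTs are valid, treatment coding with lullaby and the
shifted pairing as reference levels.

## The synthetic cohort

`synth` generates the three data streams the analysis consumes, each a pure
function of its seed.

**Songs** are verse-structured trains of pitched tone bursts (4 harmonics,
5 ms attack, exponential decay) at the metronome inter-onset interval
60/tempo. Condition defaults follow the study prompts and the observed
direction of every acoustic contrast: playsong 170 BPM, f0 268.6 Hz, RMS
0.056, and larger variability on every axis; lullaby 100 BPM, 260.5 Hz,
0.045. Variability has per-note components (timing jitter 2.0%/1.2% of the
inter-onset interval; pitch 0.8/0.45 semitones; amplitude 25%/12%) and
per-verse components (tempo 5%/3%, transposition 1.5/1.0 semitones,
loudness 30%/15%) — singing drifts between verses rather than holding a
metronomic grid, and without that drift a synthetic song would stay
phase-locked over minutes, which real singing does not. The scalar or
per-feature `variability` multiplier scales all of these; 0 gives an exactly
periodic train. Ground-truth onsets and note f0 ride along in metadata.

**EEG** is a forward model: the z-scored envelope convolved with a known
channel × lag kernel (smooth biphasic shape peaking near 80 and 200 ms;
zero-mean dipolar-like topography across channels so the coupled signal
survives average re-referencing), plus 1/f-shaped noise band-limited to
0.3–100 Hz (the typical infant-EEG spectral shape), plus square-pulse
artifacts (150–300 μV, 200–600 ms, Poisson-timed, on a random quarter of
channels). Coupled and noise parts are rescaled so their variance ratio
equals the requested snr exactly and the clean channel RMS is 20 μV. No
study-calibrated snr exists for real infant EEG; snr is an explicit dial,
and the acceptance cohort uses snr = 1.

**Behaviour**: movement proportions are Beta(μφ, (1−μ)φ) with condition
means 0.3 (playsong) / 0.1 (lullaby), precision φ = 50, and a logit-scale
dyad intercept (SD 0.3); vocabulary is negative-binomial (base mean 150
words, dispersion 5 — the real score's distribution is unpublished, so
over-dispersed counts are assumed) with log-mean slope 0.2 per SD of the
dyad's playsong tracking (or movement when no accuracies are supplied).

**What the generator does not emulate.** No vocal realism (formants,
lyrics, singer identity), no maternal movement or infant gaze, no
non-stationary artifacts other than square pulses, no volume-conduction
correlation structure in the noise, and no coupling nonlinearity. Passing
tests therefore demonstrate that the estimators recover the structure this
generator plants at realistic sizes — not that real infant EEG contains
such structure.

## Problem sizes and numerical choices

The acceptance cohort uses 30 dyads × 2 conditions with 2-minute recordings
per condition at snr 1, 400 shift permutations per subject, and the default
29-channel montage; tempo checks use 60-s trains. Simulation-based tests run
at reduced sizes chosen for precision per unit time (e.g. 200 null cohorts
for cluster-level error control at 250 randomizations; 100 replicates for
mixed-model power and calibration at 30–40 dyads with channel-averaged
accuracies). Linear solves use `numpy.linalg.solve` on the normalized
normal equations; λ = 0 with condition number above 1e12 raises rather than
silently pseudo-inverting. Beta-GLMM quadrature uses 20 Hermite nodes.
Degenerate inputs (constant factors, all-constant features, proportions at
the boundary, all-bad channels, disconnected adjacency) raise informative
errors or degrade with logged notes, as exercised by the test suite.

## Known limitations

- The cluster test assumes exchangeability under sign flips; heavy-tailed
  subject effects would make the cluster-forming threshold conservative or
  liberal in ways the synthetic cohort does not probe.
- Pulse-clarity values are not comparable to published MIR-toolbox numbers.
- The bad-channel z-score masks multiple simultaneous outliers (see above);
  real pipelines needing aggressive channel rejection should lower the
  threshold or raise the pass count.
- Envelope/EEG alignment assumes a shared hardware clock; drift correction
  is out of scope.
- The leave-one-subject-out generic-model path is intentionally not the
  default; individual models are, matching the analysis this package
  implements.
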