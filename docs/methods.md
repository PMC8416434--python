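# Methods

This note documents the models, estimators, numerical choices and
limitations behind `qeeg`. It is the design record; every number quoted
here is recomputed by the test suite or by `scripts/acceptance.py`.

## Spectral estimation

Recordings are analysed on the 19-channel 10–20 montage (FP1 … O2,
linked-mastoid reference descriptor) at 128 samples/s; higher-rate input
is polyphase-resampled (Kaiser-windowed anti-alias FIR, mean-preserving
edge padding). Artifact handling is a plain per-epoch amplitude
threshold: any 2-s epoch in which any channel exceeds ±100 μV (both
parameters configurable) is rejected, and at least 60 s must survive.
This rejector is a deliberately generic stand-in for centre-specific
clinical protocols; it is aligned to the 2-s analysis epoch so that
rejection composes exactly with the FFT windows.

The cross-spectrum accumulates 256-point FFTs of Hann-tapered windows
advanced in 64-point steps (75 % overlap) — 117 windows for a clean 60-s
record — restarting the sliding sequence at every accepted span so no
window straddles a rejected epoch. The periodic (DFT-even) Hann window
is used, matching standard Welch implementations. Per 0.5-Hz bin
(0.5–40 Hz retained) the per-channel sums Σ(a²+b²) and per-pair sums
Σ(au+bv), Σ(av−bu) of cosine/sine coefficient products are stored.

*Band power* is the window-mean of the accumulated auto-power summed
over the band's bins and normalised by 2/(L·Σw²) (L = 256 window
length, w the taper), which makes the all-band sum a Parseval estimate
of the in-range signal variance in μV²: a unit-variance white-noise
channel yields Σ bands ≈ (40−1)/64 ≈ 0.609, and an amplitude-A sinusoid
yields A²/2 in its band (both verified against brute-force filtered
oracles at 5 %).

*Coherence* is the squared magnitude of the accumulated cross-spectrum
normalised by the accumulated auto-powers, evaluated per bin and
averaged without weighting over the band's bins (a pooled-sums variant
is available as a sensitivity option). The imaginary cross term enters
as a(x)v(y) − b(x)u(y); with the alternative plus sign the single-window
value would not be identically 1 and the estimator could exceed 1, so
the minus sign is the only form consistent with a magnitude-squared
coherence. Per-bin values match `scipy.signal.coherence` with matched
windowing to ~1e-9. Bands are half-open [low, high) on the 0.5-Hz grid,
so the shared edges at 4, 8, 12, 25 and 30 Hz belong to exactly one
band, and the 1-Hz delta edge is included.

Degenerate inputs: a channel with zero accumulated power over an entire
band makes that band's coherence undefined and raises an error rather
than returning 0; a single-window record gives coherence ≡ 1 by
algebraic identity (this is why at least 60 s of data is demanded).

## Feature space

A full per-subject record is 19 × 6 band powers and 171 × 6 coherences
(1,140 values). Band powers enter classifiers as log10(power + 1e-12)
by default — spectral powers are approximately log-normal across
subjects — with raw μV² available; coherences are never transformed.
The combination grid crosses {PSD, FC, PSD+FC} with {each single band,
all six}; age, sex (male = 1, female = 0), years of education and
optionally IQ are appended as ordinary predictor columns, giving the
22–1,144 column range. Covariates are penalized like any feature by
default; `en_penalize_covariates=False` exempts them (penalty factor 0,
with the λ path anchored at the covariate-adjusted null model).

## Classifiers and cross-validation

All three classifiers z-score features inside `fit` with training
statistics only; no statistic of a held-out fold ever reaches a
training fit (checked by a fit-hash test).

**Elastic net.** Penalized logistic regression, objective
(1/n)Σ log-loss + λ(α‖β‖₁ + (1−α)/2‖β‖₂²), mixing α = 0.5 by default
(configurable in (0, 1]). The solver is a glmnet-style IRLS +
coordinate-descent path solver with warm starts down a 30-point
log-spaced λ path from the null-model λ_max (path length, floor ratio
and tolerance configurable); it is numba-compiled because the
permutation × CV workload runs hundreds of thousands of path fits.
Solutions agree with sklearn's saga solver at matched C = 1/(nλ) to
~1e-6. λ is chosen by inner stratified K-fold (default 10, reduced
automatically when a class is too small) binomial deviance, at the
deviance minimum (`lambda_rule="min"`, default) or by the
one-standard-error rule (`"1se"`). Predictive performance is reported
at the minimum; *feature-survival* extraction refits at the 1se rule —
the parsimonious convention — because stability selection at the
CV-optimal λ systematically retains dataset-level chance correlates
that persist across 90 %-overlapping folds.

**SVM.** RBF kernel with a median-heuristic bandwidth
(γ = 1/median‖xᵢ−xⱼ‖²), C selected from the fixed grid
(0.1, 0.5, 1, 5, 10) by inner-CV AUC; a linear kernel is available.
Ranking scores are margin distances; class predictions use the decision
boundary (reported through a monotone squashing so the 0.5 probability
threshold coincides with it).

**Random forest.** 500 trees by default, ⌊√p⌋ candidate features per
split, class probabilities by tree-vote fraction, impurity importances
exposed.

The outer loop is stratified 10-fold cross-validation (plain k-fold by
flag); stratification is used because clinical contrasts are often
imbalanced and unstratified folds can produce single-class test sets.
AUC is the Mann–Whitney concordance with ties at half credit;
sensitivity and specificity threshold the case probability at 0.5.
Summaries are mean and sample SD (n−1) over folds on the percent scale.
All randomness — outer folds, inner folds, bootstraps, permutations —
derives from one master seed through SHA-256 tagged substreams, so
every result is bit-reproducible.

## Survival rule and permutation test

A feature survives if its elastic-net coefficient is nonzero (exact
zeros, as produced by soft-thresholding) in strictly more than 7 of the
10 folds, i.e. ≥ 8/10; the threshold is a parameter. The report also
carries sign consistency and the mean coefficient over nonzero folds.

The permutation test shuffles group labels, re-splits the folds and
reruns the entire nested cross-validation per permutation; the p-value
is the plain fraction of null mean-AUCs at or above the observed one
(reported as "< 1/n" at zero exceedances; an add-one estimator is
available). The default is 200 permutations (1,000 for publication-grade
resolution); fewer than 20 flags the result as low-resolution. Because
observed and permuted datasets are processed identically, the p-value is
exchangeable-valid even though "best-of-21" model selection inflates the
unadjusted null AUC.

The combination sweep cross-validates all 21 combinations and selects
the highest mean AUC, breaking ties toward fewer features and then grid
order (parsimony).

## Synthetic cohorts

Each channel is a sum of six band-limited Gaussian oscillators — white
noise shaped in the frequency domain by a 4th-order Butterworth
band-pass magnitude response (steady-state equivalent of filtering;
order configurable) and normalised to a target RMS — plus 1/f-power
pink noise and white sensor noise. Defaults (μV RMS): delta 6, theta 4,
alpha 8, beta 3, high beta 1.5, gamma 1, pink background 5, sensor
noise 2 — an eyes-closed posterior-alpha-dominant profile. Amplitudes
saturate smoothly above 60 μV (bounded dynamic range), so clean
synthetic records never trip the 100 μV rejector; rejection is tested
with explicitly injected spikes.

Between-subject variability is an independent log-normal jitter
(σ = 0.5) of every (channel, band) amplitude. This value was calibrated
once so the headline contrast (alpha ×1.5 on the 8 posterior channels
Cz, P7, P3, Pz, P4, P8, O1, O2, 60 + 60 subjects) attains a best-model
CV AUC near 90 % — the clinically realistic regime — rather than a
saturated 100 %.

Group effects act on cases only: power effects multiply a (channel,
band) amplitude (power ratio = multiplier²); coupling effects add a
shared band-limited latent source with weight w to both channels of a
pair, giving in-band coherence ≈ (w²/(1 + w² + r))² with r the in-band
background-to-oscillator power ratio — monotone in w, verified against
a brute-force two-channel oracle. Covariates default to a
healthy-control profile (age 25.72 ± 4.55, 63.2 % male, education
14.91 ± 2.06, IQ 116.24 ± 10.94) with per-disorder presets (e.g. the
schizophrenia-like preset draws case IQ from 89.62 ± 17.51); covariates
are independent of the EEG effects unless an IQ–power coupling slope is
requested, which exists to demonstrate how IQ adjustment changes
results under confounding.

What the generator does *not* emulate: volume conduction / reference
leakage (baseline coherence between untargeted channels is near zero,
far below real scalp EEG), non-Gaussian transients, eye-blink or EMG
artifacts, non-stationarity, and medication or site effects. Passing
recovery tests therefore demonstrates correctness of the pipeline's
machinery, not clinical performance.

## Problem sizes in tests and the acceptance script

The suites use desk-scale analysis settings (8–15 λ path points, 3
inner folds, solver tolerance 1e-5–1e-6) — these change cost, not the
procedure. The null-calibration suite runs 50 no-effect cohorts
(40 + 40 subjects, 60 s) × 200 permutations and checks
Kolmogorov–Smirnov uniformity of the permutation p-values plus a grand
mean CV AUC within 50 ± 2 points; the recovery suite runs 10 master
seeds of the alpha-effect cohort. `scripts/acceptance.py` reports the
same quantities at 30 cohorts × 100 permutations and 5 recovery seeds
to stay within a few minutes on one CPU.

## Known limitations

- The artifact rejector is amplitude-only; real pipelines combine
  ICA/regression ocular correction with expert review.
- EDF ingestion trusts the file's channel labels and µV scaling.
- The elastic-net path solver assumes standardized inputs (handled
  internally by the estimator) and binary labels.
- `GridSearchSVM` probability output is a monotone squashing of the
  margin, adequate for AUC and boundary thresholding but not a
  calibrated probability.
- Multi-class contrasts are out of scope; any two groups can, however,
  be supplied as the two labels.
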