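# Methods

This note documents the models, parameter choices and numerical decisions
behind cardiolens, and what the synthetic benchmarks do and do not show.

## The isolation–integration classifier

Each of the L input leads is processed by its own encoder: two 1-D
convolutions (kernel 17, C = 8 channels by default, second layer stride 2)
with ReLU activations and independent parameters per lead. The stride
product of the encoder is constrained to be exactly 2, so the concatenated
feature matrix F has shape (L·C) × T/2 and channel block ℓ is a function of
lead ℓ alone. This isolation property is what makes per-lead attribution
exact rather than approximate, and it is asserted numerically in the test
suite (perturbing one lead changes no other block, to machine precision).

The integration trunk is a plain convolutional stack — two stride-4
conv–ReLU layers (kernel 9, 16 channels), global average pooling over time,
and a linear head with one sigmoid output per label. A residual trunk was
considered and rejected: skip connections add backpropagation surface
without measurable benefit at the network sizes that train in CPU minutes,
and no contract depends on the trunk's internals. Multi-label tasks use one
sigmoid head per abnormality; sex and hypertension are separate binary
models.

The network is implemented in numpy with explicit forward/backward passes
(`cardiolens.nn`). Convolution gradients are verified against central
finite differences in the tests; He-normal weight initialisation with small
random bias perturbations so that independently initialised encoders
respond distinctly even to degenerate (all-zero) input. Training uses Adam
(lr 3e-3), weighted binary cross-entropy with positive-class weight
n_neg/n_pos capped at 20, an 80/20 train/validation split, and early
stopping on validation loss (patience 5 by default); the parameters of the
best validation epoch are restored. All randomness flows from a single seed
and the run is deterministic on one machine with fixed thread settings.
Inputs are standardised per lead with training-split statistics stored on
the model.

## Saliency

Gradients are taken with respect to the **pre-sigmoid logit** of the target
label (standard practice for class-activation methods; the probability
differs only by a positive factor σ′(z) and yields the same normalised
map). Gradient averaging is per record over the temporal axis only. The
per-lead map is the ReLU of the α-weighted channel sum inside the lead's
block; upsampling to input resolution is linear interpolation by exactly 2
(nearest-neighbour available for bit-exact block maps). Normalisation is
global across all 12 leads of a record — not per lead — because dominant-lead
analysis compares mass *across* leads; per-lead normalisation would erase
exactly the signal being measured. For unlabeled queries the
argmax-probability label is explained.

## Dominant leads

Records with predicted probability strictly above τ = 0.8 count as
confident; the dominant lead is the argmax of per-lead heatmap mass, ties
broken toward the earlier lead in the standard order (DI … V6), and all-zero
heatmaps are excluded rather than assigned. The occurrence bootstrap
resamples confident *records* with replacement (B = 1000) and reports the
per-lead mean ± sd of counts. The reduced-lead subset takes leads with
strictly more than a 10% share, and reduced-lead evaluation retrains a fresh
model with L = |subset| encoders — masking the 12-lead model's inputs is
kept only as an ablation, since a device with two electrodes trains on two
leads from scratch.

## Evaluation statistics

AUC is the Mann–Whitney pair statistic (ties half-counted). Micro averages
pool TP/FP/FN across labels before forming precision/recall/F1. The G-mean
operating point maximises √(sensitivity × specificity) over the unique
scores with a ≥-threshold convention, ties to the lowest threshold. The
diagnostic odds ratio applies the Haldane–Anscombe +0.5 to all cells when
any cell is zero, with a log-normal Wald CI. Confidence intervals are
percentile bootstrap (B = 1000, records resampled, seeded); undefined
precision at zero predicted positives is reported as 0 with a warning
rather than NaN. Paired model comparison uses a sign-flip paired bootstrap
(two-sided, capped at 1). Age groups are half-open bins [0, 45), [45, 75),
[75, ∞) years.

## Survival

Kaplan–Meier estimation is delegated to lifelines. The Cox
proportional-hazards fitter is implemented in-package: Newton–Raphson on
the partial likelihood with Efron tie handling by default and Breslow
behind a flag, converged when the largest score component falls below 1e-6
(at most 50 iterations, with the iteration trace carried on failure). A
log-sum-exp shift keeps the risk-set sums stable; the shift cancels exactly
in the reported log likelihood. Wald 95% CIs are exp(β ± 1.96·SE) from the
inverse observed information. The implementation is cross-checked in the
tests against lifelines (agreement to 1e-5 on tied data) and against a
brute-force likelihood grid search. Age enters adjusted models as a
continuous covariate in years; ECG-predicted phenotypes are binarized at
the G-mean cutoff before entering survival models.

## The synthetic generator

Beats are sums of Gaussian waves (amplitude, offset from the R peak, width
per wave) mixed into 12 leads by a fixed per-wave table; the defaults give
a plausible normal morphology (dominant R in lateral leads, rS pattern in
V1, inverted complexes in AVR). Rhythm is an RR process with configurable
mean rate and coefficient of variation; repolarisation adapts to rate (T/U
centers and widths scale with the shortest plausible RR, and U waves fade
above ~110 bpm) so that fast rhythms remain physiologically separable.
Noise is a few low-frequency wander sinusoids plus white Gaussian noise at
a configurable SNR (default 20 dB); noise-free generation is available for
measurement-based validation.

Abnormality injectors follow textbook criteria, since the source clinical
labels have no published definitions: first-degree AV block draws PR in
[0.21, 0.36] s (capped so the P wave fits the diastolic interval at fast
rates); bundle branch blocks draw QRS in [0.13, 0.15] s with mirrored V1/V6
signatures (tall V1 R for right, deep V1 S and tall V6 R for left); sinus
bradycardia 40–55 bpm; sinus tachycardia 101–150 bpm; AF removes P waves,
draws RR CV in [0.18, 0.3] and adds a 4–9 Hz fibrillatory oscillation of
0.02–0.04 mV. A rule-based measurer (R-peak detection, an envelope-based
QRS width with a linear calibration fitted on clean records, narrow-peak P
detection with a width/amplitude discriminator, onset geometry from the
measured half-width) recovers each single injected abnormality on clean
records — verified at 100% over 50 seeds per label in the tests. The
generator's constants (envelope threshold 0.08 mV, P half-width cutoff
85 ms, QRS width calibration 1.538·w − 0.0538) are calibrated to the
generator's own beat model, not claims about clinical ECGs.

Cohorts default to the study population profile this package emulates:
60.26% female, 31.66% hypertensive, age 53.64 ± 17.42 years (truncated to
[18, 95]), abnormality prevalences of 1.6–2.8% each with mutually exclusive
rhythm labels, and a 3.34% seven-year mortality target. Sex appears in the
waveform as a T-amplitude (+25% male) and heart-rate (−4 bpm) shift;
hypertension as +30% V1 R amplitude and a widened P wave. Survival times
are exponential with hazard λ₀·exp(xᵀβ); the baseline λ₀ is solved by
root-finding so the expected observed event fraction matches the target
under censoring. Censor times are Uniform(0.5, 7) years (administrative cap
at 7), which reproduces the target follow-up profile of mean ≈ 3.7, sd ≈
1.9 years. Default log-hazard coefficients use the adjusted hazard ratios
the survival stage is meant to recover (e.g. ST 2.24, AF 2.22,
hypertension 1.67). Seeding splits a root `SeedSequence` into per-subject
streams, so any subset of a cohort regenerates identically.

## Problem sizes and benchmark design

The planted-saliency benchmark puts a 25 Hz, 0.35 mV cosine-tapered
transient in lead V1 at 1.0–1.5 s of an ordinary sinus-rhythm record
(T = 1024 samples at 400 Hz). The amplitude sits well above the noise floor
but below the R wave, chosen so that a correctly trained model is nearly
perfect (test AUC ≈ 1) and a faithful attribution concentrates in the
planted lead and window; it is a validation instrument, not a difficulty
benchmark. The acceptance-level run uses 500 training and 200 test records;
shared test fixtures use 160/100 — sizes at which the numpy network trains
in about a minute.

Hazard-ratio recovery uses replicate cohorts of n = 20,000 at a ~3.3%
event rate. A single Cox fit at these sizes has SE(log HR) ≈ 0.08–0.13
(few hundred events), so point estimates scatter visibly around the planted
value; the recovery experiment therefore averages ten independent replicate
fits, which brings the Monte Carlo error of the reported estimate to about
2–4% of the hazard ratio while leaving the per-cohort conditions untouched.
Bootstrap coverage of the AUC interval is checked over 200 simulations of
100 + 100 scores from unit-variance Gaussians one unit apart (true
AUC = Φ(1/√2) ≈ 0.760).

## What the synthetic benchmarks do not show

The generator produces stylised morphologies: no electrode noise artefacts,
baseline drift beyond smooth wander, paediatric or paced rhythms,
multi-episode arrhythmia within a record, or inter-subject morphology
diversity beyond the parameter ranges above. Passing the planted-signal
and hazard-recovery benchmarks demonstrates that the architecture,
saliency math, lead ranking and survival machinery are correct and
internally consistent — it does not certify diagnostic performance on
clinical ECGs, which depends on data realism no simulator guarantees.

## Known limitations

- The numpy network is CPU-scale by design; it makes no attempt to match
  the capacity of GPU-scale clinical models.
- The Breslow tie option shares the Newton solver but is exercised less
  heavily in the tests than Efron (the default).
- The interval measurer is calibrated to the generator's Gaussian beat
  model and is not a general-purpose ECG delineator.
- Combined abnormalities (e.g. first-degree AV block during tachycardia)
  can produce physiologically contradictory geometry; the consistency
  guarantee covers single-abnormality records.
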