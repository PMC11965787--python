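# Methods

This note records the models behind `ppgrhythm`, the choices that were
genuinely open, and what the simulation-based validation does and does not
demonstrate.

## Rhythm models

RR-interval (beat-to-beat) sequences are generated per rhythm class; every
interval is constrained to the physiological range [0.25, 2.5] s.

**Sinus rhythm (SR).** Near-regular intervals around 60/HR seconds with
sinusoidal respiratory modulation (default depth 4%, 0.25 Hz ≈ 15
breaths/min) plus additive Gaussian jitter (SD 20 ms). Defaults give the
gentle variability of a resting adult; cohort subjects draw HR ~ N(65, 7)
bpm, clipped to 48–90.

**Atrial fibrillation (AF).** Serially independent draws from a shifted
Gamma distribution, `RR = 0.25 s + Gamma(k, θ)`, with k and θ solved from
the requested mean (default 0.55 s ≈ 110 bpm, typical of a pre-cardioversion
ventricular response) and coefficient of variation (default 0.22). The
shift keeps a hard physiological floor; independence across beats produces
the "irregularly irregular" response. CV 0.22 is a conventional figure for
AF ventricular series; the study that motivated this package does not
characterize its population's RR statistics, so these defaults are
physiological conventions, not fitted values.

**Atrial flutter (AFL).** A fixed atrial cycle per subject, drawn
U(0.18, 0.25) s (≈ 240–330 bpm atrial rate), conducted to the ventricles at
integer ratios {2, 3, 4} with stationary probabilities (0.6, 0.3, 0.1).
Regular conduction (AFL_REG) keeps one ratio for the whole recording
(±1% uniform jitter), mimicking sinus-like regularity at an unusual rate;
variable conduction (AFL_VAR) switches ratios as a Markov chain with stay
probability 0.7, producing the multimodal RR pattern the comb-residual
feature targets. The two conduction patterns collapse to a single AFL
category for reporting.

## Waveform rendering

One two-Gaussian pulse template (systolic peak at 0.15 s, σ 45 ms; broader
dicrotic wave at 0.42 s, amplitude 0.3, σ 120 ms) is placed at each beat
onset. Pulse amplitude is reduced by β = 0.5 times the fractional deficit
of the preceding interval relative to the series mean (floor 0.2) —
shortened diastolic filling after a premature beat lowers stroke volume, so
AF recordings carry amplitude variability on top of timing variability.
Additive disturbances: baseline wander (0.3 a.u. at 0.2 Hz, random phase),
white noise (SD 0.05), and motion-artifact bursts arriving as a Poisson
process. The *pre-revision* feedback regime uses 2 bursts/min; the
*post-revision* regime (after the real-time user-feedback update the
protocol introduced) uses none. Burst duration is U(1, 3.5) s with ±8 a.u.
uniform amplitude, calibrated once so the pre-revision regime yields ≈4%
of recordings with insufficient quality — the contrast the two regimes are
meant to reproduce. Default sampling rate is 30 Hz, the frame-rate class of
a smartphone camera; recordings last 60 s.

## Cohort structure

Each subject contributes one pre-cardioversion recording on day 0 with a
rhythm drawn 85.2% AF / 14.8% AFL (the 82.1/14.3 baseline split
renormalized over the two arrhythmias), converts to SR, and records on days
1–30. Daily recording counts are Poisson(2.11) by default, reproducing the
observed ≈64.3 recordings per patient over a month with ~twice-daily
adherence. Relapse is a constant per-day hazard (default 0.05/day, chosen
so roughly half the follow-up recordings are arrhythmic, matching the
50/50 SR/AF mix of the deployed training data); after relapse all
recordings carry the pre-cardioversion rhythm. The simulated reference
("ECG-read") label equals the true rhythm except with probability 0.036 it
is uninterpretable, matching the observed rate of insufficient-quality
reference tracings. Every recording's seed is derived from the cohort seed
and recorded in the manifest, so any recording regenerates in isolation.

## Signal quality

The sufficiency rule — ≥30 usable seconds of a 1-min recording, inclusive —
is the published minimum for *reference-ECG* readability; no PPG-specific
rule is published, so the same threshold is adopted deliberately for PPG.
Windows are 5 s, non-overlapping, half-open. The per-window signal-quality
index is the mean Pearson correlation of adjacent pulse epochs
(−0.2 s…+0.3 s around each detected peak, resampled to 30 points);
threshold 0.8. Windows also require ≥3 detected pulses and all samples
within ±6 a.u. Whether the deployed quality algorithm operates on windows,
beats or whole recordings is undisclosed; the windowed design is a
standard, testable stand-in.

## Pulse detection and features

Peak detection runs on detrended segments with prominence and height
thresholds adaptive to the 95th absolute percentile, a 0.25-s refractory
distance (capping detectable rate at 240 bpm), and parabolic sub-sample
interpolation of peak times. Detection is restricted to maximal runs of
good windows so no interval bridges an artifact. Intervals outside
[0.25, 2.5] s are discarded as detection errors; fewer than 10 usable
intervals makes a recording undiagnosable (excluded as "other").

The 13 features are standard AF-discriminating irregularity statistics plus
the comb residual for AFL. Conventions for degenerate (zero-variance)
input: sample entropy, Poincaré ratio and lag-1 autocorrelation are defined
as 0. When sample entropy finds no template matches at tolerance r, it is
capped at log(n−m) + log(n−m−1), the largest value resolvable at that
series length. The comb residual scans candidate cycles on a 1-ms grid over
[0.15, 0.30] s with multiples k ≤ 6 and is normalized by the mean interval;
its brute-force equivalence is asserted in the tests. RR-entropy uses a
16-bin histogram over [0.25, 2.0] s.

## Classifier and certainty

Hyperparameters are fixed a priori — RBF kernel, C = 1,
γ = 1/(d·Var(features)) — because the deployed model is described as
trained without hyperparameter optimization but its values are not
published; the canonical defaults are recorded in the model metadata.
Features are z-scored with training-set statistics stored in the model.
The 3-class task uses one-vs-rest with inverse-frequency sample weights,
preventing the degenerate never-predict-AFL solution at the ~4% AFL
prevalence of a realistic training mix.

Certainty is the top-class Platt-calibrated posterior. Platt sigmoids are
fitted on decision values from an internal stratified 5-fold split, so the
calibration never sees decision values of points the SVM was fitted on;
Platt's prior-corrected targets keep the map bounded away from 0/1 on
near-separable data. For the binary model certainty lies in [0.5, 1] by
construction. The abstention gate is strict: certainty < 0.9 is low,
exactly 0.9 is accepted. The published certainty is described only for the
binary case; using the top-class posterior with the same gate for the
3-class task is this package's extension of that definition. Whether the
deployed certainty is a Platt-style posterior is unknown; no equivalence
with the commercial algorithm is claimed.

Models serialize to a single JSON document (support vectors, dual
coefficients, scaler statistics, sigmoid coefficients, metadata); the
round trip is exact.

## Evaluation

Exclusion reasons are assigned in fixed priority order — reference
uninterpretable → PPG quality insufficient → low certainty → other — since
no precedence is published for multiply-excludable recordings; the ledger
plus the analysis set always conserves the input count. Wilson score
intervals are used for all proportion CIs (the source's CI method is
unstated; Wilson remains well-behaved near 100%, where these metrics
live). The F1 interval applies Wilson to F1's own effective counts,
2TP/(2TP+FP+FN). Undefined margins report as undefined, never 0. χ² tests
are Pearson without continuity correction, with Fisher's exact available
for small expected counts. AUROC is computed on the analyzed
(post-exclusion) set — whether gated recordings were excluded before or
after the published AUROC is unstated, and gating-before is the
operationally meaningful choice here. Per-participant agreement
dichotomizes SR vs AF with flutter-labelled records excluded, matching the
published 263/280 analysis.

## Study orchestration and problem sizes

The default study is desk-scale: 30 training and 40 validation subjects
(~1900 and ~2560 recordings), all post-revision; the full-size
configuration (180/280 subjects, revision changepoint after validation
subject #196) is available behind a flag. Internal LOSO validation runs
for the binary AF classifier; holding out one of the few AFL subjects at
desk scale routinely leaves fewer than the 5-per-class minimum, so 3-class
LOSO is left to explicit calls. All stage seeds fan out from one master
seed via `numpy.random.SeedSequence`, and a repeated run is byte-identical
in the summary JSON. t-SNE uses perplexity 30, 1000 iterations, PCA
initialization, fixed seed; cluster separation is checked quantitatively by
silhouette score rather than by eye.

## What the simulation shows — and does not

Passing the simulated external validation (accuracy ≥ 99.7%, AUROC ≥ 0.999
on gated recordings) shows the *pipeline* is correct: quality gating,
leakage-free training, calibration, abstention and the statistics all
behave as specified under data whose ground truth is known and whose
class-conditional distributions are cleanly separated. It does not show
that real smartphone PPG is this separable: the simulator omits
arrhythmias beyond AF/AFL (ectopy, AV block), drift in device handling,
inter-device optics, skin-tone and perfusion effects, and reader
disagreement on the reference. Real-data performance claims require real
data; the simulated figures characterize the software, not the device.
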