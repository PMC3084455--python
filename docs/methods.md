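# Methods

`cohdecode` reproduces, on fully synthetic data, an fMRI multivariate
pattern analysis (MVPA) of coherent versus incoherent Gabor-path motion:
whether the direction of a drifting element can be decoded from early
visual cortex voxel patterns when — and only when — the element is part of
a globally coherent moving object, in the absence of any mean-amplitude
(univariate) difference between contexts. This note documents the models,
the parameters that matter, and the design choices made where the design
was genuinely open.

## Stimulus geometry

Five Gabor elements (carrier 2.7 cycles/°, Gaussian envelope SD 0.55°) sit
on a 160° arc of a circle, neighbouring elements separated by 5.5° of
visual angle. The circle's radius follows from the chord equation
`5.5 = 2R sin(step/2)` with `step = 160/4 = 40°`, giving `R ≈ 8.04°`. The
circle's *centre* is under-determined by the published geometry: only the
eccentricity range 4.1°–8.4° constrains it. We place fixation inside the
path circle on the symmetry axis through the middle (curve) element and
choose the fixation–centre distance by least squares against the nominal
(min, max) eccentricities. An exact match is impossible with `R ≈ 8.04°`;
the realised range is ≈ 4.08°–8.32° and is reported on every configuration
(`realised_eccentricity_range`) rather than silently pretending precision.

In the coherent context each element's carrier orientation is orthogonal
to the local path tangent, so its drift (sign set by the global rotation,
clockwise or anticlockwise) is tangential to the path. The incoherent
context swaps orientation and drift direction between the two outer
inducers and between the two inner inducers. The published description
names only the outer pair; we pair outer↔outer and inner↔inner, which
reverses the orientation sequence along the path and therefore provably
preserves the multiset of neighbouring orientation differences — the
stated requirement for the manipulation. The curve element and the
distractor (at 4.1° eccentricity, diagonally opposite the curve element,
same orientation, opposite drift) are identical in both contexts.

The display frame rate is not published; it is fixed at 60 frames/s —
the only rate at which a 30°/frame phase advance yields the stated
5 cycles/s — and exposed as a parameter of `carrier_drift_speed`.

Block schedules: a main run is a leading 19.2 s blank followed by eight
19.2 s stimulus blocks (4 conditions × 2 repetitions, uniformly random
among orders with no immediate repeat, by rejection sampling) each followed
by a 19.2 s blank; at TR 3.2 s with 6 dummy volumes this gives 108 volumes.
The element-localiser schedule (8 × 25.6 s blocks, 9.6 s fixations) gives
97 volumes. Polar angle 0° is the right horizontal meridian,
counter-clockwise positive; quadrants are open half-axes.

## Generative model for voxel time series

Voxel `v` in a stimulated ROI responds to each block with amplitude

    a_v = μ_c + s·β_c·w_v,

`μ_c` the context's mean response, `β_c` the SD of its per-voxel direction
biases, `s = ±1` the drift direction, and `w_v ~ N(0,1)` drawn once per
participant. A single signed scalar weight per voxel is the minimal model
for a two-direction experiment; context modulates the *effective* bias SD
through `β_c` rather than redrawing weights, so coherent and incoherent
patterns are correlated, as feedback-modulation accounts imply. The
amplitude train (boxcar per block) is convolved with a canonical
double-gamma HRF (gamma-density difference; peak delay 6 s, dispersion 1,
undershoot delay 16 s, ratio 1/6; mode ≈ 5 s; unit peak). Noise is
additive, Gaussian, stationary AR(1) per voxel (default SD 1.0, lag-one
correlation 0.3 at TR 3.2 s), spatially independent before smoothing.
Dummy volumes are generated with noise only and discarded by the pipeline.

Defaults (units: noise-SD = 1 signal units):

| parameter | default | meaning |
|---|---|---|
| μ_coh, μ_incoh | 1.0, 1.0 | equal mean amplitude — no univariate context effect |
| β_coh, β_incoh | 0.06, 0.0 | direction bias only in the coherent context |
| noise SD, AR(1) φ | 1.0, 0.3 | temporal autocorrelation at TR 3.2 s |
| grid | 10×10×5 voxels at 1.5 mm | two 200-voxel quadrant ROIs + two 50-voxel element ROIs |
| runs × participants | 8 × 9 | leave-one-run-out folds; df = 8 group tests |

The coherence effect size is not published; `β_coh = 0.06` was chosen once
so that coherent-direction decoding lands in the empirically plausible
55–70% band (it yields ≈ 0.66–0.69 group-mean accuracy) and is documented
as illustrative, not estimated.

What the generator deliberately does *not* emulate: spatial structure of
real voxel biases (here spatially white before smoothing, whereas real
biases have low-frequency structure — which is why smoothing helps real
decoding but slightly hurts it here), physiological noise, motion,
distortions, cortical geometry, and richer direction tuning than a signed
scalar. Passing tests therefore certify the *analysis machinery* —
calibration, unbiasedness, sensitivity — not biological realism.

## Preprocessing

Order: spatial smoothing → per-run z-scoring → lag-shifted block
averaging; the order is recorded in every run manifest. Smoothing is a
separable Gaussian, σ = FWHM/(voxel·2√(2 ln 2)), zero-padded with kernel
renormalisation so constants pass through unchanged; default FWHM 5 mm.
Z-scoring is per voxel, per run (mean 0, sample SD 1); a zero-variance
voxel's run segment becomes 0 — neutral for a correlation classifier —
with a warning rather than an error. Each 19.2 s block is averaged, after
a 1-volume (3.2 s) haemodynamic lag shift, into one pattern ("sample"):
6 volumes, half-open window, onsets are TR-aligned so index rounding is
exact. The default design yields 64 samples (16 per condition).

The univariate control GLM is per-voxel OLS on condition boxcars ⊗ HRF
plus per-run intercepts, without prewhitening (temporal autocorrelation is
knowingly unmodelled; contrasts are used descriptively at the group
level). Rank deficiency is reported with the offending columns.

## Decoding

Nearest-class-mean by Pearson correlation ("linear correlation" read as
the product-moment coefficient; the classifier inherits its invariance to
per-sample affine rescaling). Leave-one-run-out cross-validation: per
fold, voxels are ranked by the absolute two-sample pooled-variance t
between the two classes computed **on training folds only**, both training
and test patterns are truncated to the top-`n` voxels (150 for
quadrant/area ROIs, 28 for 50-voxel element ROIs — both config keys, with
a minimum-ROI-size automatic mode), class means are computed on training
samples only, and held-out samples are assigned to the more correlated
mean. Fold accuracies are averaged. Pooled (Student) rather than Welch t
is the ranking default; the choice is not published. Ties in |t| break by
ascending voxel index; exact correlation ties go to the first class in
sorted label order; undefined correlations (constant pattern) count the
sample as incorrect with a data-quality warning. Context decoding relabels
the four condition labels to two context classes, doubling per-class
samples. A `selection="peeking"` variant ranks voxels on all runs; it
exists solely so tests can demonstrate the selection bias the nested
procedure avoids (inflated null accuracy), and must never be used for
inference.

## Statistics

* Group inference: one-sample t of per-participant accuracies against
  chance, df = n−1, one-tailed (matching the directional hypothesis);
  two-sided for contrast nulls.
* Bias maps: per-voxel |t|, clockwise vs. anticlockwise across **all**
  runs within a context — deliberately not cross-validated, it is
  descriptive — with two-sided p at pooled df; summarised as the fraction
  of voxels with p < 0.05. Note a calibration subtlety: per-run z-scoring
  divides all samples in a run by a shared estimated SD, which makes this
  descriptive t slightly heavy-tailed (null fraction ≈ 0.06 instead of
  0.05 on the full pipeline). Calibration tests therefore feed the
  statistic unnormalised samples, where it is exact; applied results on
  z-scored data should be read as descriptive.
* Repeated-measures ANOVA: classical decomposition (effect error = its
  subject interaction), uncorrected dfs (no sphericity correction, as the
  reference analyses report uncorrected dfs), backed by
  `statsmodels.AnovaRM` and cross-checked in tests against a brute-force
  sums-of-squares oracle. The degenerate all-cells-equal-within-subject
  input returns F = 0 by convention (0/0 otherwise).
* Per-participant significance: exact one-tailed binomial on pooled
  cross-validated outcomes — our choice, since the original test is
  unspecified; the caveat that CV outcomes are not strictly independent is
  acknowledged (the test is mildly anticonservative in principle).

## Psychometrics

Two-interval speed judgements are fitted with
`P(test faster|x) = λ/2 + (1−λ)·logistic(β(x−α))` by binomial maximum
likelihood (multi-start L-BFGS-B over midpoint/slope initialisations,
slope log-parameterised, λ ∈ [0, 0.06] by default — the lapse policy of
standard psychometric toolboxes; the original settings are unpublished).
Speeds are log test/reference ratios throughout; PSE is the 0.5 crossing
(equal to α under the symmetric lapse), positive PSE = test perceived
slower. Flat data are flagged with the PSE pinned (uninformatively) to the
data midpoint; complete separation — the fitted curve finishing its
0.001→0.999 transition within one level gap — is flagged as a boundary
fit. The simulated-observer generator draws binomial counts from the same
family; eye-movement exclusion appears only as an optional row filter.

## Simulation sizes and determinism

A master seed spawns per-participant `SeedSequence` children, which spawn
per-run schedule and noise streams, so any participant or run is
independently re-runnable; every output directory carries a manifest
(config, seeds, pipeline order). Monte-Carlo checks use 200 null
participants (calibration and selection-bias detection), 200 independent
9-participant null cohorts (group-test rejection rate), 50 cohorts for the
dissociation, 500 null bias maps, and a 9-point PSE grid at 500
trials/level — sizes chosen as the smallest at which the Monte-Carlo error
is well below the tolerances being asserted. The dissociation check calls
its two null claims satisfied when the corresponding tests do not reject
at α = 0.01 (the directional claim uses p < 0.05); at α = 0.05 the two
nominal false-positive rates alone would cap the joint pass rate near 90%,
making a ≥95% bar unattainable by construction rather than by defect.

## Known limitations

Spatially white voxel biases make smoothing mildly harmful to synthetic
decoding (unlike real data); the GLM ignores temporal autocorrelation; the
binomial per-participant test treats CV outcomes as independent; the
bias-map t is anticonservative on z-scored data (documented above); the
psychometric simulator ignores reference-speed roving beyond treating it
as exchangeable nuisance. None of these affect the nested cross-validation
guarantees, which are enforced by construction and verified against a
deliberately broken variant.
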