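# Methods

## Problem

Cervical vertebral maturation staging (CVMS) reads a six-level ordinal
skeletal-maturity scale, CS-1 to CS-6, from the shapes of the second to
fourth cervical vertebrae (C2–C4) on a lateral cephalogram. Two
morphological trends carry the signal: the inferior border of each
vertebral body develops a progressively deeper concavity, and the C3/C4
bodies progress from trapezoidal through horizontally rectangular and
square to vertically rectangular. Because staging is a subjective visual
judgement, labels from different clinicians disagree on a substantial
fraction of cases; this package studies how that disagreement propagates
into machine-learning classifiers trained on differently-labelled versions
of the same cohort.

The pipeline: 19 annotated landmarks per radiograph → geometric feature
vector → consensus partition of a three-rater panel → five training
datasets (one per rater, Majority Voting, Complete Agreement) →
random-forest feature selection and six classifier families with
hyperparameter search per dataset → cross-dataset evaluation of each
dataset's top model on stratified 30% holdouts of the other four datasets,
summarized by mean accuracy, sample SD, and coefficient of variation
(CV = SD/mean; lower = more consistent generalization).

## Landmark scheme and features

The 19 points are assigned: C2 points 1–5 along the inferior border (3
deepest), C3 points 6–10 inferior border (8 deepest) plus 11/12
posterior-/anterior-superior corners, C4 likewise on 13–19. All geometry is
computed in image pixel coordinates (origin top-left, y down); the scheme
is data (YAML-loadable), not code.

Per vertebra the candidate features are: the vertex angle at the deepest
concavity point, the perpendicular height of that point over the
corner-to-corner chord, the enclosed border-vs-chord polygon area ("AUC",
shoelace formula — a polygon area, not a fitted-curve integral), and the
inferior-border width; for C3/C4 additionally the superior width, the
posterior and anterior edge heights, and two h/v shape ratios
(inferior width over posterior edge = "right", over anterior edge =
"left"). Age (years) and sex (female=1, male=0) complete the 24-feature
candidate vector. All features are rigid-motion invariant; lengths scale
linearly, areas quadratically, angles and ratios are scale-free. Features
are reported in raw pixels by default (the annotation tool exports pixel
coordinates and no calibration object is assumed); an optional
normalization divides lengths by the C3 inferior width.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis depends on,
not radiographic appearance.

**Latent maturity.** Each subject carries a continuous maturity m; a
subject of true stage s has m uniform on [s−0.5, s+0.5). Vertebral shape
parameters interpolate linearly between per-stage anchors, so subjects
near a stage boundary are morphologically intermediate — the cases real
panels disagree on.

**Morphology anchors** (editable YAML): concavity depth as a fraction of
the inferior width ramps 0 → 0.04 → 0.08 → 0.12 → 0.15 → 0.18 with onset
at stage 2 for C2, 3 for C3, 4 for C4; C3/C4 h/v ratio means
(2.0, 1.9, 1.7, 1.4, 1.0, 0.8); taper (superior/inferior width)
0.8/0.8/0.8/0.9/1.0/1.0. Subject-level variation: body width lognormal
around 60 px (σ=0.08), multiplicative depth noise (σ=0.25), ratio noise
(σ=0.10), taper noise (SD 0.03), isotropic annotation jitter (default SD
1.5 px), a small random tilt (SD 5°) and translation per subject. These
magnitudes are free stand-ins chosen once for realistic overlap between
adjacent stages; they are not estimates of any real sample.

**Demographics.** Per-stage counts default to (201, 151, 181, 328, 294,
225), total 1380; ages are truncated normals on [4, 21] y with per-stage
means (8, 10, 12, 13.5, 15, 17) and SD 1.5; sex is Bernoulli with
female:male = 1.12:1.

**Raters.** Two noise families share the `RaterProfile` container.

*Categorical*: a rating equals the true stage with probability `p_exact`,
otherwise moves to an adjacent stage (directional split `adjacent_bias`,
boundary mass reassigned to the valid side) or, with probability `p_far`,
two or more stages away. Errors are independent of the subject's features.

*Perceptual* (default): a rater reads m through Gaussian noise (SD σ,
stage units) — with probability `p_far` ≈ 0.10 a "blunder" read with SD
1.2 — and discretizes at personal stage boundaries k + 0.5 + δ_k. The
default boundary shifts make rater 1 and rater 2 share an over-staging
convention at the CS-3/4 boundary while rater 3 under-stages at CS-2/3 and
CS-4/5, so pairwise agreement is heterogeneous, as observed panels' is.
Repeat-session reads reuse the primary perceptual error with correlation
ρ. The perceptual family makes errors case-correlated (everyone struggles
near boundaries) and rater-systematic (boundary shifts are learnable from
features); both properties are required for consensus-trained models to
out-generalize single-rater models rather than merely out-score them.

**Calibration.** `calibrate_profiles` bisects σ (or 1−p_exact) with common
random numbers until the mean pairwise inter-rater weighted kappa on
`n_sim` simulated subjects sits at the centre of the target range
[0.62, 0.78], then bisects ρ (or `p_repeat`) for the intra-rater target
[0.86, 0.92]. Unattainable targets raise an error reporting the achievable
range. Under the defaults the calibrated panel lands near κ ≈ 0.69–0.71
pairwise, routes ≈ 90–93% of subjects into Majority Voting and ≈ 8–10%
into complete disagreement, and puts ≈ 30–33% into Complete Agreement.

## Agreement statistics

Weighted kappa uses disagreement weights |i−j|/(k−1) (linear, package
default) or squared (quadratic). Linear is the default because, under the
unimodal error families above, it is the scheme for which the reported
agreement ranges and the reported consensus-partition rates are jointly
attainable; quadratic weighting is so forgiving of adjacent confusions on
a six-point scale that matching κ ∈ [0.62, 0.78] would require error rates
incompatible with ~92% majority-voting coverage. When both raters are
constant and equal, expected disagreement is zero and kappa is defined as
1.0 with a warning. Confidence intervals are subject-level nonparametric
bootstrap (percentile 2.5/97.5; SD of replicates).

The consensus partition is strict 2-of-3 semantics: Complete (all equal),
Partial (exactly two equal, consensus = the shared value; no seniority
weighting), Disagreement (all distinct, excluded from consensus labels).

## Modelling

Stratified 70/30 split per stage (largest-remainder rounding; a singleton
stage goes to train with a warning). Feature selection fits a 300-tree
random forest on the training split only and keeps features with impurity
importance ≥ the mean importance (a `top_k` rule is available); age and
sex compete as ordinary candidates. Six families are tuned by random
search (default budget 50 configurations) with inner stratified CV on the
training split and refit on the full split: logistic regression, MLP,
random forest, k-nearest neighbours, SVM (RBF/linear), and gradient
boosting (histogram implementation). Scale-sensitive families are
standardized inside the pipeline; tree ensembles are not. Search spaces
are deliberately desk-scale (e.g. 50–200 trees, SVM C ≤ 100, ≤ 120
boosting iterations) and editable. Ties in top-model selection break by
fewer features used, then a fixed family order, and are flagged.

## Generalization

Each dataset contributes a stratified 30% holdout (largest remainder per
stage; 1380 → 414). Each top model is scored on the four holdouts of other
provenances; any holdout subject that sat in that model's training split
is excluded from that cell first (preserving "unseen" semantics), with
exclusion counts reported. Summaries use the sample (n−1) SD —
recomputation of the published per-column statistics shows only that
convention reproduces all ten printed SD/CV cells — with means printed as
percentages (one decimal) and SD/CV on the proportion scale (two
decimals). Models rank by ascending CV.

## Study-scale choices

The qualitative-reproduction runs (tests and `scripts/acceptance.py`) use
the full cohort size n = 1380, search budget 15 per family, 2-fold inner
CV, and 10 replicate seeds (3 in the acceptance script); these sizes were
chosen once as the package's desk-scale study design. Under them the
consensus orderings reproduce: the Complete Agreement dataset's top model
has the highest in-dataset test accuracy (≈ 0.79–0.85 vs ≈ 0.49–0.58 for
single raters) and the smallest cross-dataset CV in the generalization
report. The absolute accuracies of the original study are properties of
the real radiographs and are not reproduction targets here.

## What the synthetic tests do and do not show

Passing tests demonstrate that the pipeline's statistics and procedures
behave correctly and that the consensus advantage emerges under a
plausible, calibrated model of panel behaviour. They do not validate the
morphology anchors against real anatomy, the landmark scheme against any
particular annotation protocol, or the absolute accuracy levels
achievable on clinical cephalograms. Real-image effects — projection
distortion, calibration, landmark detection error structure — are out of
scope by design.

## Numerical notes

Angles clamp the normalized dot product to [−1, 1] before arccos and are
defined on (0°, 180°]; degenerate geometry (zero-length angle arms,
zero-length chords, zero body heights) raises errors naming the subject.
All randomness flows from explicit seeds (`numpy.random.Generator`); equal
configuration and seed reproduce byte-identical outputs. Invalid sampled
hyperparameter configurations (e.g. more neighbours than training
subjects in a fold) are skipped during search.
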