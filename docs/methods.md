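# Methods

## The model

White-matter brain age is estimated per diffusion map by an eight-block 3D
convolutional network. Blocks 1–5 each apply a 3×3×3 convolution (stride 1,
'same' padding), 3D batch normalisation, 2×2×2 max pooling (stride 2, floor
division, no padding) and ReLU; block 6 is a 1×1×1 convolution with batch
normalisation and ReLU; block 7 flattens the tensor, applies dropout
(training only) and a fully connected layer to a feature vector; block 8 is a
linear regression over the features concatenated with covariates. Channel
widths default to [32, 64, 128, 256, 256, 64] and the feature vector to 100
entries. The pooling arithmetic (kernel 2, stride 2, floor, no padding) is
the unique choice taking a 91×109×91 grid to 2×3×2 after block 6; the
block-7 input is then 64·2·3·2 = 768.

Single-map networks take (sex, scanner) as two scalar covariates; scanner
enters as a single numeric site code, matching the covariate-slot count of
the fused design. ICV is used only at fusion. The five-map model reuses the
frozen block-7 features of the five single-map networks: the fused input is
[features×5, sex, scanner, ICV] (503 entries at default width) and its block
8 is fitted by ordinary least squares; a ridge fallback (with logged
regularisation strength) exists only for rank-deficient designs. Refitting
the fusion head never touches per-map parameters (bit-identity is asserted in
tests).

### Numerical implementation

The network engine is written directly in NumPy: convolution is an im2col
matrix product chunked along the depth axis (bounded memory at the full
91×109×91 scale), pooling is sequential pair-wise maxima per axis with argmax
bookkeeping, and batch normalisation keeps running statistics (momentum 0.1,
eps 1e-5) for evaluation mode. All gradients are exact and are checked
against central finite differences in float64 in the test suite. Training
uses Adam (default lr 3e-3, batch 16) on an L1 objective — the natural choice
when the evaluation metric is MAE; squared error is a config option. The
output bias is initialised to the mean training age. After gradient
training, block 8 is refitted in closed form by least squares on the training
features; since block 8 *is* a linear regression this is its exact optimum
and stabilises short desk-scale runs (it can be disabled via
`TrainConfig.refit_head=False`). Dropout is active only in training mode;
evaluation-mode features and predictions are deterministic, and a fixed seed
reproduces training bit-for-bit under a fixed BLAS threading configuration.

Inputs are z-scored per volume by default (configurable off); the synthetic
maps therefore carry their age signal in spatial pattern as well as mean
level.

### Small grids

Five pooling stages annihilate any axis shorter than 2⁵ = 32 voxels, and
constructing the default network with such an input is an error. The
desk-scale preset (`NetworkSpec.desk_scale()`: 24×28×24 grid, channels
[8, 16, 16, 32, 32, 16], feature dim 3) instead sets `allow_small_axes`,
under which an axis that has reached extent 1 passes through the remaining
pooling stages unchanged (24 → 12 → 6 → 3 → 1 → 1). The full-scale
91×109×91 → 2×3×2 trace is unaffected. The desk feature dimension is kept
very small so that the fused OLS head (5·d + 3 + 1 parameters) retains a
healthy sample-to-parameter ratio at a few hundred training volumes,
comparable to the ratio the full-scale design enjoys on tens of thousands.

## Bias correction and metrics

Brain-age predictors underfit at the extremes (regression dilution): the old
look young and the young old. We fit ŷ = αy + β by OLS on the left-out
validation set and invert, ŷ_co = (ŷ − β)/α, on all later predictions,
assuming (α, β) generalise. On the fit set this is an algebraic identity:
the OLS of ŷ_co on y has slope 1 and intercept 0, and corr(ŷ_co − y, y) = 0,
to machine precision. MAE may *increase* under correction; both values are
reported, never hidden. Longitudinal scans are corrected with the same
baseline-fitted model (one consistent correction avoids era confounds), and
refitting on test data is deliberately not offered. Performance is MAE,
Pearson r between age and prediction, and — separately labelled — the
Spearman correlation between gap and age (the bias diagnostic).

## The synthetic cohort

The generator emulates the statistical skeleton of a late-middle-aged
community imaging cohort. Defaults: ages uniform on 45–83; 45.8% male; three
scanner sites; ICV ~ N(1500, 150) cm³; college education 49.1%; APOE ε4
allele counts with probabilities (0.722, 0.255, 0.023); risk-factor
prevalences hypertension 0.504, diabetes 0.055, hypercholesterolemia 0.245,
obesity 0.190, smoking 0.381; 9% of participants flagged "unhealthy"
(excluded from training/validation and routed to the test split, carrying an
extra +0.5 y gap). The planted gap is

    true_gap = Σ_k factor_k·offset_k + male·obesity·1.0 + N(0, 3.2²)

with offsets (diabetes 1.390, hypertension 0.871, smoking 0.689,
hypercholesterolemia 0.311, obesity 0). The obesity damage is male-only by
construction; its footprint in category-level models (a VRS≥3 × sex
interaction ≈ 0.57 = 1.0 × P(obese | VRS≥3)) *emerges* rather than being
planted, which keeps the per-factor interaction models unbiased. An optional
`vrs3plus_sex_offset` knob can plant a category-level male offset directly.
The 3.2 y individual heterogeneity is calibrated so that the corrected gap's
dispersion lands near the ~3.5 y reported for real white-matter brain-age
gaps once prediction error is added; recovery-oracle tests use 1 y noise,
where planted effects are sharply identified.

Maps are sums of six fixed Gaussian blobs: each map m has a static base
field plus an age-coupling field W_m (voxel-mean exactly 1, spatially
non-uniform) scaled by slope_m·(effective_age − 64) — FA decreasing
(−0.003/y), MD/AxD/RD increasing (+0.004/+0.0035/+0.0045/y), MO quadratic
(nonmonotone, hence a deliberately weak single-map predictor — it anchors the
"fusion helps, worst map hurts least" ordering) — plus a smooth
participant-specific field shared across the five maps (within-participant
correlation) and i.i.d. voxel noise (sd 0.02). Because W_m is spatially
structured, the age signal survives per-volume z-scoring. The voxel-mean
intensity slope equals the configured slope exactly, giving a closed-form
recovery oracle. No anatomical realism (tracts, lesions, scanner physics,
registration artefacts) is attempted — passing tests demonstrate correct
*machinery*, not transferability to real DWI.

Cognition: each domain's latent score is −b_d·true_gap − Σ c′·factor +
age/sex/education terms + N(0, 0.85²), with per-test noise (sd 0.4) and
fixed raw-score scales; b defaults (speed 0.025, memory 0.008, executive
0.018) and direct paths (obesity→speed 0.103; smoking→executive/memory) are
planted analogues of reported effect sizes. Reversed tests (reaction time,
both trail-making tests, pairs-matching errors) are sign-flipped on the raw
scale, so the scoring module must flip them back. The longitudinal subset
(fraction 0.1262) advances age by N(2.25, 0.12) years (truncated positive)
and the gap by +0.1 y (sd 0.2) beyond ageing — a near-null drift, so
factor → gap-change analyses are expected to be null. Follow-up cognition is
regenerated from the updated state; practice effects are not modelled.

The emulated predictor used by the statistical layers ("latent-gap
shortcut") is ŷ = centre + 0.7·(age + true_gap − centre) + N(0, 1),
reproducing regression dilution so that bias correction has real work to do.
All randomness derives from a single config seed via keyed generator
streams; identical config ⇒ byte-identical cohort, maps, splits.

## Risk, cognition and inference conventions

VRS is the count of the five binarised factors, categorised 0/1/2/≥3 and
dummy-coded against 0; any missing factor makes VRS missing (complete case).
APOE is three-level by ε4 count but enters regressions as the ordinal count,
matching its single coefficient slot; sex is female=0/male=1; scanner is the
numeric site code. Cognition tests are z-scored against the full baseline
analysis sample (the least-assumption reference), domains are available-case
means of their constituents (speed: reaction time, trail A, symbol digit;
memory: numeric memory, pairs matching; executive: trail B, fluid
intelligence) and global cognition weights the three domains equally.

All models are OLS on complete cases with age, sex, scanner and APOE
controlled (education added for cognition outcomes); CIs are classical
t-based 95% intervals. The sex-moderation models (2b–f) add one factor × sex
interaction at a time to the five-factor model; the within-level sex
contrast of model 1b is a linear combination of coefficients with a
delta-method standard error. Four cognitive outcomes give a Bonferroni
threshold of 0.05/4 = 0.0125.

Mediation is the product-of-coefficients decomposition: M ~ X + C gives a,
Y ~ X + M + C gives (c′, b); ACME = a·b, ADE = c′, total = ACME + ADE (an
identity in this linear, no-interaction model — an exposure–mediator
interaction hook exists but is off). Uncertainty: nonparametric
case-resampling bootstrap, 5000 samples by default, percentile intervals
(BCa was considered and not needed for these smooth statistics); bootstrap
p-values are twice the smaller tail proportion relative to zero; resamples
with a constant exposure are redrawn and logged. The bootstrap solves both
normal-equation systems for all resamples in batched einsum form, so 5000
draws at n≈5000 take seconds.

## Problem sizes used by tests and scripts

Desk-scale CNN checks train five maps on a 400-participant cohort
(24×28×24, 3 epochs) — a few CPU-minutes; effect-recovery models run at
n=5000 via the latent shortcut; mediation coverage uses 200 replicates of
n=1000 with 600 bootstrap draws each; the pipeline smoke preset is n=200 on
a 12×14×12 grid. These sizes make the full suite run in roughly ten
CPU-minutes while leaving every assertion comfortably powered.

## Known limitations

* The maps are statistical phantoms; nothing about tract geometry, lesion
  load, scanner physics or registration error is represented.
* Risk factors are independent Bernoulli draws — real factor correlations
  (and continuous severity) are deliberately not modelled, which makes
  planted effects identifiable but understates real-world collinearity.
* The desk-scale network is far narrower than the full design and its
  absolute MAE/r values are not comparable to biobank-scale results.
* Batch-norm statistics are those accumulated during the short training run;
  the closed-form head refit absorbs most of the resulting calibration
  error, but very short runs still depend on it.
* The bootstrap treats rows as exchangeable; no clustering by scanner or
  family structure is supported.
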