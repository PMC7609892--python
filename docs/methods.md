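# Methods

`lrfusion` implements likelihood-ratio (LR) evidence evaluation for
two-class problems of the kind that arise in forensic toxicology: a panel
of continuous biomarkers measured on known positive (e.g. chronic alcohol
drinker) and negative individuals, from which a calibrated LR must be
produced for a new measurement.  This note records the models, the
numerical choices, and what the synthetic data can and cannot show.

## The statistical problem

The evidential quantity is the likelihood ratio
`LR = f(E | H1) / f(E | H2)` for the two competing hypotheses (class
memberships).  Working on posterior odds with prior odds fixed at 1, a
binary logistic regression supplies `LR = p/(1-p)` directly from its
fitted log-odds, so every classifier in this package reports its evidence
as an LR, a log10 LR, a posterior at user-supplied prior odds, and an
ENFSI-style decade-based verbal label.

The difficulty that motivates the penalized fitters is **perfect
separation**: when some linear combination of predictors classifies the
training data without error, the logistic MLE does not exist — slopes
diverge, reported standard errors become orders of magnitude larger than
the coefficients, and the implied LRs saturate at 0 or infinity.
Biomarker panels are prone to this precisely when the markers are good.

## Separation diagnosis

`detect_separation` decides separation *exactly*, by linear feasibility
rather than by symptoms.  One LP over directions (w, c) maximizes
`sum_i min(margin_i, 1)` subject to all class-signed margins being
nonnegative (features standardized internally for conditioning; variables
unbounded, so any strictly positive margin rescales to 1).  An optimum of
n certifies complete separation, a positive optimum below n certifies
quasi-separation (boundary points remain), and 0 certifies overlap in
every direction.  The witness direction is returned and, for complete
separation, classifies the training rows perfectly.  The classical
SE/|coefficient| ratio (threshold 10^3) is additionally reported from the
MLE fit as a corroborating symptom, never as the decision rule.

## The three separation-robust fitters

**Firth (Jeffreys-prior) logistic regression** maximizes
`l(b) + 1/2 log det I(b)` via the modified-score equations
`X'(y - p + h(1/2 - p)) = 0` (h = hat diagonals), Newton steps with
step-halving on the penalized log-likelihood.  Defaults: score tolerance
1e-6, at most 2000 iterations.  The generous cap is deliberate: on
near-collinear fusion-score matrices the penalized likelihood has a flat
ridge and the iteration legitimately needs several hundred steps.  The
fit runs on internally standardized features; because the Jeffreys
penalty is equivariant under affine reparameterization (the log-det
shifts by a constant), back-transformed coefficients maximize the
original-scale objective exactly.  For an intercept-only model the
penalized score has the closed-form root `p_hat = (k + 1/2)/(n + 1)`,
which the tests pin; single-class labels are allowed in that one case
(boundary shrinkage is the point of the penalty).

**Elastic net** maximizes `(1/N) l(b) - lambda * P_alpha(b)` with
`P_alpha(b) = sum_j [(1-alpha)/2 b_j^2 + alpha |b_j|]` over the slopes
only (intercept unpenalized), by cyclical coordinate descent with
soft-thresholding inside an IRLS quadratic approximation, active-set
iteration with a verifying full sweep, and warm starts along the lambda
path.  Features are standardized to mean 0 / SD 1 (population SD, the
GLM-NET convention); coefficients are reported back on the original
scale.  At the IRLS fixed point the solution satisfies the exact
stationarity/subgradient (KKT) conditions of the penalized likelihood,
which both the test suite and the acceptance script audit at 1e-6 on
random instances; the implementation also agrees with R glmnet to ~1e-8
on a reference problem.  Default mixing is alpha = 1 (lasso), consistent
with fusion fits that drop most variables.

**Lambda selection** uses stratified k-fold (default 5) cross-validated
binomial deviance on a 100-point geometric grid from lambda_max (smallest
lambda with all slopes zero; the grid top is inflated by 1e-9 so the null
model holds there despite float rounding) down to 1e-4 * lambda_max.  Two
rules are provided: `"min"` (deviance minimizer, ties to the sparser
side) and the default `"1se"` (largest lambda within one standard error
of the minimum).  The 1-SE default was chosen because it is the standard
parsimony rule and, empirically under a pure-noise null (n = 60, k = 5,
100 datasets), it keeps the model to at most one spurious slope in ~97%
of datasets versus ~81–88% for the plain minimizer; it also calibrated
the fused LRs better in the end-to-end study.  Fold fits run at a looser
coordinate tolerance (1e-7) than reported fits (1e-10), since held-out
deviance is insensitive to trailing decimals.

**Bayes GLM** computes the posterior mode under independent Student-t
priors by prior-augmented IWLS with an EM update of the latent prior
variances (`V_j = (df * s_j^2 + b_j^2)/(df + 1)`, the scale-mixture
E-step).  Following the weakly-informative-prior recommendation of
Gelman and colleagues, inputs are centered and rescaled to SD 0.5, slopes
get a Cauchy prior (df = 1) with scale 2.5 and the intercept scale 10.
The fixed point is a stationary point of the marginal t-posterior, which
the tests verify against brute-force grid maximization.  Standard errors
come from the curvature of the augmented system; no posterior sampling is
attempted.

## Scores and fusion

Per-variable scores are `s_j = log f(x_j|H1)/f(x_j|H2)` with class-
conditional densities estimated either as Gaussians (sample mean and SD,
divisor n-1) or by Gaussian-kernel KDE with Silverman's bandwidth
`h = 0.9 min(sigma_hat, IQR/1.34) n^(-1/5)` (quartiles by linear
interpolation; if exactly one of sigma/IQR is zero the other is used, the
min being undefined there; both zero is degenerate data).  Every density
evaluation is floored at 1e-300 so scores remain finite under arbitrary
extrapolation.  Scores are natural-log internally; base-10 appears only
in reports.  Fusion is affine-invariant to that choice (coefficients
rescale inversely), which a test verifies.

The fusion model `logit(p) = b*0 + b*1 s1 + ... + b*k sk` is fitted by
any of the fitters above, on a *validation* set disjoint from the
*training* set used for the densities.  The segregation is enforced:
shared rows raise an error, and variables whose within-class training
values are constant are dropped with a warning rather than aborting.

**Extrapolation control.**  Outside the training support a floored
density ratio is dominated by bandwidth asymmetry and the floor itself —
finite, but evidentially meaningless, with magnitudes up to
|log 1e-300| ≈ 690.  Left uncapped, one such score on an outlying test
item can swing the fused LR by hundreds of orders of magnitude and a
single replicate's Cllr into the tens while accuracy stays high.  The
fusion stage therefore clips each variable's scores (for both the
validation fit and prediction) to the envelope of scores the training
rows themselves produce: an extrapolated item can be "as strong as
anything seen in training", never stronger.  This is the usual capping
discipline of forensic calibration; the raw per-variable score function
remains unclipped for users who want it.  A `clip_scores=False` switch
restores raw behaviour.

## Discriminant baselines

LDA (pooled covariance, divisor n-2) and QDA (per-class covariances,
divisor n_c-1) model each class as a Gaussian.  Their reported LR is the
pure class-conditional density ratio; class priors (empirical by default,
equal on request) are kept out of the LR and folded back in only for the
posterior used by the 0.5-threshold class call.  Singular covariances
receive a logged ridge jitter of `1e-8 * trace/k`, escalated up to eight
times before erroring.  The implementation is checked against a
hand-computed Bayes-rule oracle and against scikit-learn's QDA
posteriors.

## Metrics

Confusion-matrix measures (precision, recall, specificity, accuracy,
error, F1) follow the standard definitions; 0/0 cases return an
"undefined" marker and are excluded from harness averages with a count.
Cllr is

    Cllr = 1/2 [ 1/N1 sum log2(1 + 1/LR1_i) + 1/N2 sum log2(1 + LR2_j) ],

base 2 by default (the forensic-comparison convention; the base is a
flag).  LRs are saturated at 10^±300 before Cllr with a saturation
counter.  The class-call threshold is p >= 0.5, ties to positive,
equivalent to LR >= 1 at prior odds 1.  Verbal labels use the decade
bins (1, 10], (10, 10^2], ... with "<=" on the upper edge, mirrored
through 1/LR below 1.

## The comparison harness

Each replicate draws a stratified random 50/40/10
train/validation/test split.  Stratification uses class-wise
largest-remainder allocation (ties toward earlier partitions), which
keeps every partition's class count within one observation of the global
proportion; a non-stratified mode exists behind a flag.  Fusion methods
fit densities on train and the fusion GLM on validation; plain
classification methods fit on train ∪ validation; everything is scored
on test only.  One master seed spawns per-replicate child seeds
(`numpy.random.SeedSequence`), so all methods see identical partitions
and reports are bit-reproducible.  Replicates where a fitter raises or
fails to converge are excluded from that method's averages and counted;
separation flags are tallied independently, so the plain-MLE column
reports its (expectedly universal) separation rate even though its
metric averages are empty on a separated panel.

The default grid is the 10-method study: {Firth, elastic net, Bayes} ×
{Gaussian, KDE} fusion, plus LDA, QDA, Firth and plain-MLE
classification.

## Synthetic data

`generate_biomarker_like` emulates the structure of a chronic-alcohol
biomarker panel: k = 8 positively skewed, mutually correlated markers on
n = 125 individuals with class balance 0.5 (labels Bernoulli per row).
Marginals are lognormal via a Gaussian copula (equicorrelation 0.3 by
default, any positive-definite matrix accepted) with log-scale SD 0.6
and a class-location shift of 1.0 for the two designated "direct
biomarker" columns and 0.5 for the rest — moderate, realistic contrasts
chosen once.  When `separation_gap > 0` (default 0.5) the positive class
is shifted additively in the separating columns until
`min(pos) - max(neg) >= gap`, reproducing exactly the
perfect-separation pattern that defeats the MLE; with gap 0 no shift is
applied and all marginals overlap.  All randomness uses numpy's PCG64
generator, so a seed pins a dataset bit-for-bit.

What the generator does *not* emulate: real concentration scales and
toxicological cut-offs, heavy-tailed measurement error, missingness,
batch effects, or label noise.  Passing tests therefore demonstrate the
statistical machinery (separation robustness, calibration, the
qualitative superiority of penalized KDE fusion by Cllr) on data with
the right shape, not performance claims about any real assay.

## Problem sizes and runtime

The shipped end-to-end study runs n_cv = 50 replicates of the full
10-method grid on the n = 125 default panel — about five minutes on one
CPU, dominated by the per-replicate elastic-net lambda cross-validation.
The bias simulation uses 1000 replicates at n = 30, and the KKT audit 50
random instances; these sizes give stable Monte-Carlo conclusions while
keeping the whole suite comfortably runnable on a laptop.

## Known limitations

- Binary response only; no weights, offsets, or missing-data handling.
- Bayes GLM reports a mode and curvature, not a posterior distribution.
- Bandwidths come from Silverman's rule only; no CV bandwidths.
- The elastic net at lambda = 0 on separated data inherits the MLE's
  divergence and stops at its iteration cap with `converged=False`.
- The fusion stage drops degenerate variables silently (logged) rather
  than imputing or regularizing them.
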