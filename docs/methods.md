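# Methods

## Model

phylou treats the per-gene summary statistics of a gene family — mean
expression paired with one mean methylation feature (promoter TSS200 or
gene body) across control individuals — as a continuous trait vector that
evolved along the family's sequence-based phylogeny. The trait follows a
multivariate Ornstein-Uhlenbeck (OU) process

    dX(t) = -A (X(t) - θ) dt + Σ dW(t)

with drift matrix A (units 1/time), optimum θ, diffusion Σ and a root
state x0. Along a branch of length t the transition is Gaussian with mean
`exp(-At) x0 + (I - exp(-At)) θ` and variance `∫₀ᵗ exp(-As) ΣΣᵀ exp(-Aᵀs) ds`.
At every node the process splits into independent copies, so the joint tip
law is multivariate normal; the between-gene, between-trait covariance of
tips i and j is `exp(-A(Tᵢ - tᵢⱼ)) V(tᵢⱼ) exp(-Aᵀ(Tⱼ - tᵢⱼ))`, where Tᵢ is
the root-to-tip depth, tᵢⱼ the depth of the most recent common ancestor
and V(t) the marginal variance propagated from the root. Branch lengths
(expected replacements per site) are used directly as process time; A and
Σ absorb any overall time scale.

Four model classes are compared:

| class            | drift A                      | root                           |
|------------------|------------------------------|--------------------------------|
| BM               | 0                            | free x0, zero variance         |
| OU stationary    | eigenvalues > 0              | x0 = θ, stationary variance    |
| OU non-stationary| eigenvalues > 0              | free x0, zero variance         |
| OUBM             | zero rows for the BM traits  | free x0, zero variance         |

Under OUBM the methylation trait (by default) drifts neutrally while
expression is pulled toward an optimum and tracks the Brownian trait
through the off-diagonal drift entry.

Within-population variation is added to the model covariance diagonal as
uncorrelated measurement error. The tip datum is a group *mean*, so the
default augmentation is the squared standard error s²/n; the source
phrasing is ambiguous between s² and s²/n, so raw s² is available via
`measurement_error="variance"`. The model is agnostic to whether
methylation means are on the beta or M-value scale.

## Numerics

Segment variances use the eigendecomposition A = PΛP⁻¹ with the Hadamard
factor `(1 - exp(-(λᵢ+λⱼ)t))/(λᵢ+λⱼ)`, replaced by its limit `t` whenever
|λᵢ+λⱼ| < 1e-8 (this is what makes the OUBM zero eigenvalues exact rather
than special-cased). In the eigenbasis the propagated variance telescopes
along any root-to-node path, so the variance at a node is a closed form in
its depth and the global covariance assembles without per-node recursion.
When the eigenvector matrix is ill-conditioned (1-norm condition estimate
above 1e8, e.g. a defective Jordan block), the code falls back to
scaling-and-squaring matrix exponentials with adaptive quadrature
(`scipy.integrate.quad_vec`) for segment variances and explicit node
recursion; the stationary covariance falls back to the continuous
Lyapunov equation. Eigen-decompositions of 1×1 and 2×2 drift matrices use
closed forms. The log-likelihood is evaluated through a Cholesky
factorization, never an explicit inverse; a non-positive-definite
augmented covariance raises an error reporting the smallest eigenvalue.

## Fitting

Each class has a smooth unconstrained parametrization: A lower-triangular
with a positive diagonal (softplus, smoothly saturated at 100 per unit
branch length — beyond that, adaptation is instantaneous on the tree scale
and the likelihood has a noncompact ridge with drift and diffusion growing
together, on which no interior optimum exists), ΣΣᵀ through its Cholesky
factor. The triangular restriction means eigenvalues are real and equal to
the diagonal; full complex-eigenvalue drift is not fitted by default. The
mean parameters (θ and/or x0) enter the likelihood linearly and are
profiled out exactly by GLS at every objective evaluation, so the numeric
search covers only the covariance parameters (3-6 dimensions for k = 2).

The search is multi-start: a moment-based start (Brownian variance scaled
from the sample covariance for BM; a stationarity-consistent ΣΣᵀ ≈ 2α₀ ×
sample covariance with α₀ = 2/height for the OU classes), a near-Brownian
boundary start for the OU classes (which guarantees the nested-model
property logLik(OU) ≥ logLik(BM)), and seeded random perturbations. Each
start runs Powell's direction-set method (relative tolerance 1e-10, capped
evaluations); if no start certifies convergence the incumbent is polished
by L-BFGS-B and bounded Powell continuations, accepting either the
optimizer's own certificate or a full cycle that improves the
log-likelihood by less than 1e-8 (relative). Powell replaced the more
common simplex search because Nelder-Mead stalls far from the optimum on
these profiled surfaces and numeric-gradient line searches abort on the
drift ridges.

Classes are compared by AICc = -2 logL + 2p + 2p(p+1)/(n-p-1) with n the
number of scalar tip observations (n_tips × k) and p counting all free
parameters including the profiled means: for k = 2, BM has 5, stationary
OU 8, non-stationary OU 10 and OUBM 8. Ties within 1e-6 go to the class
with fewer parameters.

## Detection

The fitted control process is simulated along the tree (exact Gaussian
edge-wise sampling; default 200,000 replicates, experiments use 10,000)
and, per gene and trait, the simulated-minus-observed-control differences
form the null. The two-sided empirical p-value with a pseudo-count is
p = (#{|null| ≥ |case - control|} + 1)/(R + 1), ties counting toward the
null; p can never be exactly 0. Significance (default p < 0.05, strict)
labels cells as DEG / DMG_promoter / DMG_body, with the sign of the
difference giving the up/down direction. No multiple-testing correction
is applied by default — single-family evidence feeds a cross-family
network — but Benjamini-Hochberg is available. Case measurement noise is
not added to the null: the observed case-control difference is compared
directly to simulated-minus-true control differences.

Because both the observed and the null statistic subtract the *same*
observed control values, the p-values are exactly calibrated
(conditionally on the controls) when the null ensemble comes from the
generating process. When the ensemble comes from a maximum-likelihood
refit, the plug-in null is slightly too tight — variance and mean overfit
by roughly (n-p)/n — which at 20 tips, k = 2 and 8 parameters inflates
the 5% type-I rate to ≈ 7.5-8%. Both figures are computed by the
validation experiments; REML-style corrections are a known remedy and are
out of scope here.

## Synthetic data

`phylou.synth` generates every input with known truth: ultrametric Yule
trees (exponential waiting times, rate 1/unit time by default; presets
mirror signalling-family sizes of 6, 29 and 36 tips), control tables as
one process realization plus Gaussian noise on the group means (default
s² = 0.01 with n = 20 individuals — low noise relative to process spread),
and case tables as an *independent* realization of the same process with
selected (tip, trait) cells shifted by a chosen multiple of the process
standard deviation at that tip. Using an independent realization makes
unshifted cells true nulls for the empirical p-value scheme. The default
bivariate truth pairs a beta-scale methylation optimum (0.5) with a
log-scale expression optimum (5), selection strength 2 per unit height and
correlated diffusion. What the generator does not emulate: realistic 450K
beta-value marginals, probe-level affinity structure, batch effects, or
model misspecification (the fitted class family always contains the
truth) — passing tests therefore validate the machinery, not robustness
to real-data artifacts.

## Similarity stage

Term probability counts the distinct genes annotated to a term or any
descendant (transitive closure; a direct-children-only reading is a
switch) over the annotated corpus; information content is the natural-log
negative. Term similarity is `2·IC(MICA)(1 - p(MICA)) / (IC(t₁)+IC(t₂))`
(0 when the denominator vanishes), where the MICA is the common ancestor
with maximal IC, ties broken by identifier. Gene similarity is the
best-match average (mean of row and column maxima) over the *directly*
annotated term sets; disease-set consistency lifts the same best-match
average to gene pairs (mean and max aggregations are switches — the
aggregation used for disease matrices is not uniquely determined by the
method description). Diseases with no significant genes yield missing
(not zero) consistency entries.

## Validation experiment sizes

The experiments behind `scripts/acceptance.py` and the acceptance tests
use: 20 random instances (≤ 8 tips) for the quadrature oracle; one 6-tip
family with 200,000 replicates for the Monte-Carlo covariance check; 100
univariate Brownian (σ² = 2, no noise) and 100 bivariate strong-selection
families of 30 tips for model recovery (selection restarts = 1,
evaluation cap 400 — selection only needs AICc
gaps, not fully polished optima); 50 univariate replicates for optimum
recovery; 100 families of 20 tips at 10,000 replicates for calibration;
and 30 shifted families for power. These sizes keep each experiment's
Monte-Carlo error well inside the asserted margins.

## Known limitations

- Only real-eigenvalue (triangular) drift is fitted; oscillatory
  adaptation is representable by the process classes but not reached by
  the default optimizer parametrization.
- Regime shifts (multiple optima on one tree) and more than two jointly
  modelled traits are out of scope, as are confidence intervals on the
  fitted parameters.
- The ML plug-in null is anti-conservative at small family sizes (see
  Detection above); marginal p-values near the threshold should be read
  as suggestive, consistent with how the cross-family network uses them.
- Trees are taken as given (rooted, with branch lengths); inference of
  the tree itself, outgroup handling and rooting are the caller's
  responsibility.
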