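# Methods

This note records the statistical models implemented, the numerical choices
made where the design was genuinely open, what the synthetic generator does
and does not emulate, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

All methods operate on a subjects × features matrix. Volumes are flattened
through a binary mask in fixed row-major order (last axis fastest), surfaces
as left-hemisphere-masked then right-hemisphere-masked vertices concatenated,
square networks as the strict upper triangle in row-major cell order
(n(n−1)/2 features). Masking, vectorization and their inverses are exact
round trips; harmonized networks are written with zeros on the diagonal and
lower triangle by default (`network_output: symmetric` mirrors them for
tools that expect symmetry). Site labels come from the mandatory `SiteName`
demographic column; site order is first-appearance order, which fixes all
dummy/one-hot coding and makes repeated runs byte-identical. A covariate
column that parses as numeric for every subject is treated as continuous,
anything else as categorical (dummy-coded, first level dropped); missing
covariate values are an error — no imputation.

## ComBat

Model per feature *v*: `y_ijv = α_v + X_ij·β_v + γ_iv + δ_iv·ε_ijv`.
Estimation follows the canonical reference implementation so that outputs are
exchangeable with the R/Bioconductor one (verified to machine precision on a
frozen fixture in `tests/data/`):

- design = site one-hot block plus covariates (no global intercept);
  identifiability via the sample-size-weighted zero-sum constraint, so
  α_v is the weighted mean of the per-site means;
- pooled residual variance σ²_v divides by N (not N−k);
- parametric EB: method-of-moments hyperparameters (normal prior on γ,
  inverse-gamma on δ²), coupled posterior fixed-point iteration, relative
  change < 1e-4, cap 100 iterations (best iterate returned with a warning on
  non-convergence);
- nonparametric EB: for each feature, the likelihood-weighted average of all
  other features' raw (γ̂, δ̂²) — parallelizable over features with
  worker-invariant results;
- degenerate priors (zero cross-feature variance within a site) keep the raw
  estimates: there is nothing to borrow.

Two behaviors worth knowing: in-sample removal drives the residual site-mean
F statistic *below* 1 (the estimates are fit on the same data), and EB
shrinkage leaves a small residual site mean whose size grows with the site's
noise level and shrinks with the true cross-feature spread of site effects —
a bias/variance trade the method makes on purpose. A second ComBat pass
therefore still moves values by ~2% of an SD (re-shrinkage of sampling
noise); exact idempotence is not a property of EB ComBat.

## CovBat

Stage 1 is ComBat (identical code path). Residuals around the retained
intercept+covariate structure are scaled per feature by their own SD, PCA is
computed by SVD of the centered matrix (sign fixed by forcing each
component's largest-magnitude loading positive), and the leading components
that explain 95% of variance (default; exact count or other fractions
configurable) get a per-score, per-site location/scale adjustment. The
default score adjustment does **not** pool across scores with EB: the
handful of retained scores are few and heterogeneous, and shrinkage toward
their common prior measurably dilutes the one real adjustment
(`score_eb=True` restores the EB variant). Reconstruction adds back the
untouched trailing scores, the per-feature scale, and the mean structure;
with the score step disabled this reproduces the ComBat output to 1e-8,
which the tests verify.

CovBat equalizes per-site score *variances*; site differences that live in
the off-diagonal within-site score covariances (eigenvector mixing, worst
when eigenvalues are close at the given n) survive. This is a limitation of
the method, not the implementation, and bounds how close to chance a
sensitive covariance probe can get.

## SMA

Each source site is mapped to the target by per-feature affine transforms
`y ↦ a·y + b` (a > 0) minimizing the squared MMD between transformed source
and target samples, with an RBF kernel `k(x,y) = exp(−‖x−y‖²/2h²)` and the
median-heuristic bandwidth on the pooled sample. The estimator is the biased
V-statistic. Optimization is deterministic first-order descent with
backtracking from the moment-matching start (a₀ = sd_T/sd_S,
b₀ = mean_T − a₀·mean_S); only improving steps are accepted, so the fitted
MMD never exceeds the start's. Tolerance 1e-6, cap 500 iterations.

Subsampling mode stratifies subjects by the Zcut rules (0 = categorical by
distinct value; ascending cutpoints = half-open upper-inclusive bins),
repeatedly draws subgroup-frequency-matched subsamples from source and
target (matching the target's mix; source cells empty at the target are
excluded with a warning), fits per draw, and takes the per-feature median
over draws (default R = 100). Target-site rows pass through bit-identical.
The recommended target site maximizes n_site × subgroup coverage, ties
broken by size then first appearance.

The affine family is this package's operationalization; it can null additive
and multiplicative site effects exactly but has a hard cap on what
subsampling can demonstrate under pure composition confounding: aligning a
source with group-1 fraction p₁ to a target with fraction p₂ shifts the
source by (p₁−p₂)·β, so the pooled group-effect estimate is attenuated by
the factor 1−(p₁−p₂)² in expectation (16% at 70%/30%), never more. A
transform family that can move mass between mixture modes (quantile/OT-style)
would distort more; the config keeps the transform behind one function so
such a family can be swapped in.

## Linear models

GLM: per-feature least squares on intercept + covariates + sum-to-zero site
dummies; the fitted site term is subtracted, so the grand mean and covariate
effects are preserved and site effects sum to zero exactly. LMM: per-feature
random-intercept model fitted by REML through statsmodels; the predicted
BLUPs are subtracted. Boundary solutions (σ²_u → 0) get exact zero BLUPs;
optimizer failures fall back to the GLM estimate for that feature with a
warning. Fewer than three sites triggers a warning (the variance component
is weakly identified) but completes. BLUPs are shrunk relative to the GLM
fixed effects on balanced designs, which the tests check.

## ICVAE

Architecture per 512-feature block (wider matrices are split into 512-wide
blocks, the last zero-padded and the padding stripped on output): encoder
512→256→128→64 (tanh) with 64-dim mean and log-variance heads; decoder
mirrors it, taking the latent sample concatenated with the site one-hot;
adversary 512→32→32→n_site (tanh, softmax output). Features are standardized
per block before training and the transform inverted after decoding.

Loss: `L = L_recon + α·L_marginal + β·L_prior − γ·L_adv` with α=1, β=0.1,
γ=10. Normalizations, which the weights only make sense relative to:

- `L_recon` — squared Euclidean distance between input and reconstruction,
  averaged over the batch (sum over the 512 features). A per-feature mean
  instead makes the γ=10 adversarial gradient dominate per-element gradients
  by ~two orders of magnitude; the game then rewards "confidently wrong"
  adversary states and reconstruction collapses.
- `L_prior` — analytic Gaussian KL to N(0, I), mean over the batch.
- `L_marginal` — squared RBF MMD between the batch of encoder posterior
  samples and fresh N(0, I) draws (the decoder's generative latent
  marginal), bandwidth by the median heuristic on the detached batch.
- `L_adv` — adversary softmax cross-entropy (accuracy itself is not
  differentiable). The adversary is trained in alternating steps to minimize
  this CE; the generator's −γ·L_adv term maximizes it.

The adversarial game is evaluated on reconstructions decoded with *randomly
drawn* site codes each step (reconstruction itself still uses the subject's
own code). Decoding with own codes only lets the decoder cancel latent site
signal against the one-hot path — the adversary is fooled while
target-decoded output still carries the source site; random codes make that
cancellation impossible, so the pressure lands on the latent representation.

Training: Adam, learning rate 1e-3 for both players, one adversary step per
generator step, default 200 epochs, batch size 16 — small batches give
desk-scale cohorts (n of order 100–300) enough generator updates per epoch
for the game to converge. All sampling (reparameterization, prior draws,
random codes, shuffling) flows from the run seed; identical seed and config
reproduce the loss trace exactly. Harmonization encodes with the posterior
mean (no sampling) and decodes with the target one-hot, so it is
deterministic given a trained model. Per-block network parameters are saved
under `out_dir/params`.

Caveats: the in-training adversary memorizes small cohorts, so its own
accuracy is not a useful invariance metric — use the cross-validated linear
probe (`site_separability_score`) on the harmonized output instead. The
method sees no covariates, so biological effects are retained only insofar
as they occupy latent structure the reconstruction needs; with γ=10 the
economics favor removing site structure only when it is a small fraction of
per-feature variance (the realistic regime), and strong per-feature site
offsets will partially survive.

## Synthetic generator

`SyntheticSpec` draws `y = intercept + X·β + γ_site,v + δ_site·ε` with
per-feature site offsets γ_site,v ~ N(γ_site, τ²) (τ = `gamma_tau`; the EB
model itself posits this spread — τ=0 makes cross-feature variance pure
sampling noise and maximizes EB shrinkage bias), optional site-specific
equicorrelated covariance sub-blocks (several sub-blocks give the covariance
site effect more than one direction), optional shared low-rank latent
factors (site-independent structure: imaging features are strongly
inter-correlated, and the ICVAE needs site-free structure to reconstruct),
site-dependent covariate distributions for confounding designs, and Gaussian
or scaled-t noise (the heavy-tailed option exercises the nonparametric
ComBat rationale). All ground truth is returned with the data; recovery
tests never re-estimate it.

What it does not emulate: spatial autocorrelation on a real brain grid,
physiological structure of ALFF/connectivity values, site-by-covariate
interactions, longitudinal repeats. Passing tests show the estimators invert
the generating model they assume; they do not certify performance on real
rs-fMRI.

`site_separability_score` is the site-effect detector: stratified split-half
CV, logistic regression on standardized features; `quadratic=True` appends
all pairwise feature products (the site mean of x_i·x_j is the site
covariance, so covariance effects become mean shifts in the product map)
with within-training-fold screening to the 100 most discriminative columns.
Note that after in-sample harmonization the probe can score *below* chance:
removing full-sample site means makes train-half residuals anti-correlate
with test-half residuals.

## Study sizes used in tests and the acceptance script

ComBat parity: 2 sites × 20, p=10, against a frozen `sva::ComBat` output.
ComBat recovery: 3 sites × 50, p=200, γ ∈ {−1,0,1} (τ=0.3), δ ∈ {0.5,1,2},
Age effect 0.5. CovBat: 2 sites × 100, p=60, ρ=0.8 vs 0 on 20 features in
two sub-blocks, averaged over 5 replicates × 3 CV splits. SMA: N(2,2²) →
N(0,1), 200/site, 8 features × 3 replicates; confounded design 70%/30%
group-1 at 150/site. Linear: 6 sites × 30, p=25. ICVAE: 3 sites × 50, p=512,
site offsets ±0.22 SD over 10 shared factors (85% of noise variance), 100
epochs. These sizes keep every full run in tens of seconds while holding
Monte-Carlo error comfortably inside the stated tolerances.
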