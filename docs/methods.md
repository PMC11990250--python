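# Methods

`deltacca` analyses coupled growth in two longitudinal imaging modalities.
Each subject contributes a baseline and a follow-up map per modality (for
example gray-matter density from T1-weighted MRI and fractional anisotropy
from diffusion MRI). The pipeline derives per-subject change maps, reduces
them to principal-component features, extracts maximally correlated latent
growth components with linear CCA and with a deep CCA autoencoder (DCCAE),
attributes components to input features by occlusion, and relates
components to cognition/behavior change scores with site-random-intercept
mixed models. Because the kind of cohort data this targets is
controlled-access, all empirical claims in this repository are made on
synthetic data with planted structure; the generator is first-class,
tested code.

## Preprocessing

A voxel mask keeps voxels whose cross-subject **baseline** mean strictly
exceeds a threshold (default 0.2, taken literally as `>`); the same
baseline-derived mask is applied to both timepoints. The change matrix is
follow-up minus baseline at in-mask voxels, one row per subject, columns
in C-order raster of the mask. Each modality's change matrix is centered
(not scaled — voxelwise values within a modality share units) and reduced
to K = 100 principal components. Component signs are fixed so the
largest-|loading| entry is positive, making results seed-stable; PCA is
fitted on all subjects before the train/test split, which mirrors the
analysis order this pipeline reproduces and is a known mild leakage
caveat.

## Linear CCA

Weights are the top-k directions of the whitened cross-covariance
`T = (S_x + r I)^{-1/2} S_xy (S_y + r I)^{-1/2}` (SVD route; the test
suite cross-checks against an independent generalized-eigenproblem
solution). Training variates are rescaled to unit sample variance, paired
correlations are sign-fixed nonnegative, and the largest-|u| entry of each
component is positive. The default ridge `1e-4 · trace(S)/p` exists for
numerical stability only. Defaults follow the study design: k = 20
components, an 80/20 train/test split, and a dual-split screen that calls
a component significant only when the correlation p-value (two-sided
Pearson t-test, `t = r sqrt(n-2)/sqrt(1-r^2)`) is below alpha/m = 0.05/20
= 0.0025 in **both** splits. Per-component t-tests are used rather than
sequential Wilks/Bartlett tests because the screen is defined on the
p-value of each correlation.

### Recovering planted population correlations

Estimating the planted canonical correlations of the generator is a
different task from running the k = 20 pipeline, and the distinction
matters at p = q = 100: with n = 3000 (train 2400), unregularised sample
CCA inflates null correlations to roughly `sqrt(p/n) + sqrt(q/n) ≈ 0.4`,
so unplanted directions overfit the train split harder than a rho = 0.2
signal and displace it in the ordering, while a single n = 600 test split
measures any correlation only to sd ≈ 0.04 (some draws realize a factor
correlation of 0.14 for a planted 0.2 — a ceiling no estimator can beat).
The recovery protocol therefore fits CCA at the planted rank with ridge
equal to the average feature variance `trace(S)/p` — shrinkage toward the
partial-least-squares regime, where the planted directions dominate the
cross-covariance — and averages held-out correlations over 5 generator
seeds. Under this protocol the population values (0.6, 0.4, 0.2) are
recovered within ±0.05.

## DCCAE

Two per-view MLP encoders (default p → 100 → 20, tanh hidden layer,
linear output) and mirrored decoders are trained by minibatch gradient
descent (batch 256, 150 epochs, learning rate 0.01) on

    (1 - lambda) * L_corr + lambda * (MSE_x + MSE_y),      lambda = 0.08,

so the correlation part carries weight 0.92. `L_corr` is the negative sum
of the top-k singular values of the ridge-whitened cross-covariance of
the encoded minibatch (batch-centered, 1/(n-1) scaling); its gradient is
the closed form obtained by differentiating singular values, verified
against central finite differences to 1e-4 in the tests. The networks are
plain numpy; no GPU is involved, and training is deterministic given the
seed. After descent a plain CCA is fitted on the full-training-set
encodings; those post-hoc weights define the latent components and
enforce the unit-variance and cross-orthogonality constraints exactly,
since enforcing them inside minibatch descent is not otherwise specified.
Hyperparameters can be tuned by 5-fold cross-validation maximizing the
mean sum of the first 10 validation-fold correlations (default grid:
lr ∈ {0.01, 0.001}, lambda ∈ {0.04, 0.08, 0.16}); diverging
configurations score -inf and ties keep the earlier grid entry.

Two numerical choices deserve emphasis:

- **Input scaling.** Each view is divided by a single scalar (the RMS
  feature standard deviation of the training data, stored in the model).
  A global scalar keeps tanh units out of saturation while preserving the
  relative variance structure that the reconstruction term uses to anchor
  encodings to high-variance (signal-bearing) directions; per-feature
  z-scoring destroys that structure and measurably invites memorisation.
- **Covariance ridge r_x = r_y = 0.5** (as a fraction of the unit average
  feature variance). With a near-zero ridge the whitening step amplifies
  low-variance nonlinear directions, and the network learns
  batch-consistent spurious correlations: on linear synthetic data the
  train top-5 mean reached 0.64 while the held-out mean collapsed to
  0.05. At 0.5 the full model matches plain CCA on linear data and is
  non-inferior to its own linear ablation on tanh-mixed data, which is
  the behavior the ablation analysis expects.

The linear ablation removes all hidden layers, leaving a single affine
map input → latent with mirrored decoder. On linear data its held-out
correlations match plain CCA's (the 20-dimensional bottleneck plus
post-hoc CCA is in fact slightly better conditioned than raw
100-feature CCA, so small positive gaps are expected).

## Occlusion attribution

A feature's contribution to each latent dimension is the mean over
samples of the latent shift caused by setting that raw input column to
zero (before any internal centering or scaling), all other features
unchanged — for 100 input features and 20 latent dimensions, a 100 × 20
contribution matrix per view. The baseline is exactly zero, not the
feature mean; signed values are stored and absolute values are used only
for ranking (top_k defaults to 5, ties broken by lower feature index).
For a linear encoder with weights W this reduces analytically to
`-mean(x_j) · W[j, :]`, which the tests assert to 1e-8. Occlusion
operates in PCA-feature space, where the models' inputs live. Linear
component weights can be scattered back through the PCA basis into the
voxel mask for display, signs preserved; naming anatomical regions is out
of scope.

## Outcome association

Associations are estimated one component at a time with a linear mixed
model: outcome change ~ component + age + sex, random intercept per
collection site, fitted by REML with Wald tests. No multiple-testing
correction is applied to these p-values (a caveat inherited from the
analysis design this mirrors). The default quasi-Newton optimizer in
statsmodels can return fixed effects inconsistent with a boundary (zero)
site-variance estimate, so boundary or non-converged fits are polished
with Powell's method; at the boundary the fit then equals OLS to
~1e-8. Variance explained by a combined component set is
`100 · (R2m_full − R2m_covariates)`, where R2m is the marginal
(fixed-effects) proportion of variance `var_f / (var_f + var_site +
var_resid)`; the increment can come out marginally negative through REML
variance re-estimation and is clamped at zero with a warning. Whether a
marginal, conditional or plain-OLS R² is meant by "variance explained"
is genuinely open; the marginal-increment definition is this package's
documented choice. CCA and DCCAE components are compared by all-pairs
Pearson correlation, retaining |r| > 0.15 — absolute value because
component signs are arbitrary between methods.

## Synthetic data

The generator plants k shared latent factors z_j ~ N(0,1). The X-side
factor is z_j itself; the Y-side factor is
`rho_j z_j + sqrt(1 - rho_j^2) w_j`, so the population canonical
correlation of pair j is exactly rho_j. (Applying the attenuation to both
views would square the correlation.) Features are orthonormal loading
columns scaled by `loading_scale` (default 10) times the factors plus iid
N(0, noise_sd²) noise (default 1), giving a per-view factor-recovery
ceiling of `loading_scale / sqrt(loading_scale² + noise_sd²) ≈ 0.995`.
With `tanh` mixing the nonlinearity is applied to the factor-driven
signal only, so linear CCA still detects attenuated coupling. Outcomes
are `loadings · z + age and sex effects + site intercept + N(0,1)
residual`, with age uniform on [108, 132] months, sex Bernoulli(0.5),
sites uniform with N(0, site_sd²) intercepts. Defaults mirror the study
scale: 3302 subjects, 100 features per view, three cognition and eight
behavior outcome columns. The noise level and effect sizes of the real
cohort are unknown; the defaults are plausible placeholders exposed in
the config.

The voxel-map stand-ins place a constant-value blob (0.5) on a low
background (0.05) so subject jitter can never flip a voxel across the
0.2 mask threshold, and the planted change — rows of a coupled-view
matrix rescaled to max |change| = `change_scale` < 0.45 — survives the
round trip through masking and subtraction exactly.

What the generator does **not** emulate: real GM/FA spatial covariance,
MNI geometry, scanner/site effects on the images themselves, motion or
lesion artifacts, and non-Gaussian feature noise. Passing tests therefore
demonstrate the correctness of the estimators under the planted model,
not robustness to real-data pathologies.

## Problem sizes and determinism

Tests and the acceptance script run at n = 500–3302 subjects and 4–100
features per view, sizes at which every stage completes in seconds on one
CPU while keeping sampling error small relative to the asserted
tolerances; stochastic claims are averaged over 5–20 seeded replicates.
All randomness flows through numpy `SeedSequence`, so identical seeds
reproduce results bit-for-bit.

## Known limitations

- PCA before the train/test split leaks test-set second moments into the
  feature basis (documented above).
- The dual-split Bonferroni screen controls false positives but its
  power depends on the test-split size; with 20% held out, correlations
  below ~3/sqrt(0.2 n) are undetectable.
- Plain SGD with the stated learning rate is the only optimizer; there
  is no early stopping (an epoch-level abort on non-finite loss aside).
- Mixed models support a single random intercept (site); no random
  slopes, no crossed designs, no mediation/moderation models.
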