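# Methods

## Problem setting

Candidate lung-nodule patches from CT are classified nodule vs non-nodule.
In the hybrid design this package supports, two convolutional backbones each
produce a high-dimensional feature vector per 64×64 ROI; the discriminative
work happens downstream: dimensionality reduction, cross-network feature
fusion, and a kernel classifier whose hyperparameters are found by swarm
search.  The package implements that downstream chain (and the image
preprocessing upstream of feature extraction) as reusable, seeded
components.  Backbone training and real CT data are out of scope; the
feature extractors are a pluggable interface fed here by synthetic
generators.

## ROI preprocessing

A patch is cropped as a half-open `size × size` window whose geometric
center is the candidate location (`start = center − size//2`, zero-padded at
image borders; coordinates 0-based, row-major).  Binarization uses the
maximum-entropy (Kapur) criterion: the threshold `T ∈ [0, 255]` maximizes
`H(<T) + H(≥T)`, where each term is the Shannon entropy of the histogram
restricted to one side and renormalized.  Conventions that the criterion
itself does not fix:

* sides are `< T` / `≥ T`, matching the binarization rule `pixel ≥ T → 1`;
* a threshold leaving either side empty is excluded (entropy of an empty
  distribution is undefined, and edge thresholds would otherwise win
  spuriously on near-two-level images);
* `0·log 0 ≡ 0` inside a side; ties break toward the smallest `T`;
* a constant patch raises an error rather than returning an arbitrary value.

Mask cleanup keeps the 8 largest foreground components under
8-connectivity — read as a component *count* of eight, with 8-connectivity
adopted as the blob-mask convention; equal-sized components are ordered by
the raster index of their first pixel so results are deterministic.

## CBAM attention

Channel attention pools the `C×H×W` map globally (average and max), passes
both descriptors through a shared two-layer MLP (reduction ratio `r`, ReLU
between layers, no biases), sums, and gates channels with a sigmoid.
Spatial attention stacks the channel-wise average and max maps and gates
locations with a sigmoid of a `k×k×2` cross-correlation (zero-padded
"same"). Defaults `r = 16`, `k = 7` follow the original CBAM formulation;
the operators here are inference-only tensor math with user-supplied or
seeded-random weights — there is deliberately no training loop.  Because
both gates are sigmoids, attention weights lie strictly in (0, 1), so the
composed operator is shape-preserving and never amplifies a feature — the
invariants the test suite checks.

## PCA and CCA fusion

PCA (centering, no per-feature scaling — deep activations share units) is
fitted per block on the training split; the cumulative variance
contribution rate `(λ₁+…+λⱼ)/Σλ` decides how many dimensions to keep
(default 98, clamped to the available rank).

CCA solves the whitened-SVD form of the canonical correlation problem: with
per-block covariances `S_mm`, `S_nn` and cross-covariance `S_mn` (sample
covariance, ddof 1), the SVD of `S_mm^{-1/2} S_mn S_nn^{-1/2}` yields
correlations `ρ` (clipped to [0, 1], descending) and directions scaled so
every canonical variate has unit sample variance.  Numerical choices:

* a relative ridge `1e-12 · trace(S)/dim` on each auto-covariance keeps the
  Cholesky factorizations positive definite for rank-deficient inputs while
  leaving `ρ` invariant to about 1e-6 under invertible linear transforms of
  either block (a larger ridge measurably breaks that invariance, which is
  a property the package promises);
* signs are fixed so the first nonzero loading of each `W_m` column is
  positive, with `W_n` flipped jointly so `ρ` stays nonnegative;
* pair selection counts `ρ ≥ ρ_min` inclusively (default threshold 0.8);
* serial fusion concatenates the selected variates of both views
  (`2·l₁` columns); parallel fusion sums them (`l₁` columns);
* PCA and CCA are fitted on the training split only and applied frozen to
  held-out data.

## Mixed-kernel SVM

`K_mix = γ·K_poly + (1−γ)·K_rbf` with `K_poly = (xᵀy+1)^d`,
`K_rbf = exp(−‖x−y‖²/2g²)`; both summands are PSD, so any `γ ∈ [0, 1]` is a
valid kernel (endpoints included, recovering the pure kernels exactly).
`d` is fixed at 3 and excluded from the search.  Training solves the
standard soft-margin dual on the precomputed Gram matrix via SMO; the model
records dual coefficients, the bias (averaged over unbounded support
vectors), and a directly recomputed worst-case KKT violation as its
convergence certificate, so a truncated solve is visible in the artifact it
produces.  Features are used as the fusion stage emits them, with no extra
scaling.  Labels map nodule → +1, non-nodule → −1.

## IPSO hyperparameter search

Particles move in `(log₂C, log₂g, γ)` — `C` and `g` in log₂ space because
their meaningful ranges are powers of two (`2^±9`, `2^±7`), `γ` linear in
[0, 1].  Defaults: 20 particles, 200 iterations, `ω_s = 0.9`, `ω_e = 0.4`,
`c_max = 2.5`, `c_min = 0.5`, `V_max = 0.2 ×` range per dimension, positions
clipped (not reflected) at the bounds, `r₁, r₂` drawn per dimension.

The adaptive inertia rule assigns `ω_e` to particles whose fitness exceeds
the swarm average and
`ω_s − (f_i − f_max)(ω_s − ω_e)/(f_avg − f_max)` to the rest, clipped to
`[ω_e, ω_s]`; the degenerate swarm (`f_avg = f_max`) gets `ω_e` for
continuity with the upper branch.  Learning factors follow
`c₁ = c_max(1 − (t−1)/T)` and `c₂ = c_min(1 + (t−1)/T)`.  Setting a
constant (or linearly decaying) inertia with fixed `c₁ = c₂ = 2` recovers
standard PSO, which is the baseline in the optimizer comparison.
Termination is the iteration budget, with an optional early stop at a
target fitness.  Non-finite fitness values are warned about and treated as
−∞.  Identical seeds give bit-identical traces.

The SVM fitness is mean stratified 5-fold CV accuracy with folds fixed by a
seed.  The polynomial base matrix and pairwise distances are precomputed
once per dataset, so each evaluation only assembles the mixture and fits
five folds.  Per-fold SMO effort is capped (20 000 iterations): corners of
the search box (large `C` on a raw cubic-polynomial Gram) otherwise take
tens of seconds each, and a truncated fit simply earns the accuracy it
achieves, which penalizes rather than favors those corners.  The final
model is refit with a 200 000-iteration cap and its true KKT residual
recorded.

## Synthetic generators

**Images.**  Positives are bright ellipses (radius range 6–12 px) centered
on a 64×64 canvas over a dark background; negatives are elongated dilated
streaks mimicking vessels; both get additive Gaussian noise (sd 8 intensity
units by default).  These emulate the *geometry* the preprocessing stage
must handle — blob vs streak, speckle from noise — not CT texture,
intensity calibration, or annotation formats, so passing preprocessing
tests says nothing about radiological realism.

**Feature pairs.**  Shared latents `h ~ N(0, I_s)`; view scores
`z_M = h + (δ/2)y`, `z_N = ρ∘h + √(1−ρ²)∘ε + (δ/2)y` map to `p`- and
`q`-dimensional features through random orthonormal loadings (QR of a
Gaussian matrix) plus isotropic noise (sd 0.2).  With `δ = 0` the
population canonical correlations approximate the planted `ρ` exactly, and
correlation-recovery checks use that setting: a nonzero class shift is a
mixture component that mechanically inflates observed canonical
correlations above the planted values.  The class shift is added to *both*
views' latent scores (not to the shared latent alone) so that each view
carries the full class signal and the second view contributes information
beyond the first — matching the premise that correlated cross-network
features are discriminative; with the shift confined to the shared latent,
the second view would be a conditionally uninformative degraded copy and
fusion could not help.  Defaults (`n = 1140`, `p = q = 98`, `s = 3`,
`ρ = (0.9, 0.7, 0.5)`, `δ = 2`, balanced labels) mirror the scale of the
fused deep-feature study the pipeline is designed around.

## Pipeline and problem sizes

`run_pipeline` derives independent per-stage seeds from one root seed
(splitting, folds, swarm, generator), stamps reports with a config hash,
and never lets test-split data touch PCA/CCA/IPSO fitting.
`compare_optimizers` runs RBF-SVM+PSO (γ forced to 0), MKL-SVM+PSO, and
MKL-SVM+IPSO on the same split with one shared swarm configuration, so
fitness-evaluation budgets are identical by construction.

End-to-end checks run at 1000 samples with an 8-particle × 8-iteration
swarm; the tuning-vs-grid comparison uses 250 samples, a 9×8×5 grid (360
evaluations) and a 10×6 swarm (70 evaluations); the full 20×200 swarm
budget is exercised on the cheap sphere objective.  These sizes are the
package's chosen desk-scale study conditions: large enough for stable
metrics, small enough that the whole suite runs in about a minute.

## Known limitations

* The deep-feature extractors themselves (backbones, fine-tuning, Grad-CAM
  inspection) are out of scope; CBAM here is an operator, not a trained
  module.
* Metrics on synthetic data say nothing about performance on real CT
  archives;
  the generators plant idealized Gaussian structure with isotropic noise.
* The SVM dual is solved by SMO with finite tolerance; the recorded KKT
  residual, not the solver's silence, is the convergence statement.
* Null-model test accuracy on a 200-sample split fluctuates with binomial
  sd ≈ 0.035; chance-level checks therefore average a few seeded runs.
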