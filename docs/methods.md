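# Methods

## Model

`baryimpute` treats each missing peptide intensity as arising from one of
two mechanisms and estimates it under both before combining:

* Under the **MAR** assumption the intensity matrix is approximately
  low-rank: runs are linear combinations of a few latent expression
  profiles, so a missing entry can be reconstructed from the rest of the
  matrix. The reconstruction is the softImpute-ALS completion
  `X ≈ ABᵀ` minimizing `½‖P_Ω(X − ABᵀ)‖²_F + λ/2(‖A‖²_F + ‖B‖²_F)`.
* Under the **group-specific MNAR** assumption the value is below the
  detection limit in its run, so it is drawn from a Gaussian placed in
  the left tail of the run's observed distribution:
  `N(x̄_k − s·σ̂_k, (w·σ̂_k)²)`.

The final estimate is the Fréchet mean (barycenter) of the two estimates
under squared-Euclidean distance, which reduces to the per-entry convex
combination `X′ = α_MAR·X_MAR + α_MNAR·X_MNAR`. The weights are set per
peptide from the entropy of mixing of its observed-value pattern:
`EBM_i = Σ_g m_ig log m_ig` (natural log; `m_ig` = observed fraction in
group g). `EBM_i` is finite iff every group contains at least one
observation; a non-finite value is taken as evidence of group-specific
censoring and flips the weights toward the down-shift estimate.

Assumptions worth stating explicitly: runs are independent (fractionated
samples must be merged before imputation, otherwise the low-rank model's
independence assumption is violated); intensities are log2 scaled before
modelling; the down-shift draws are independent across runs (the mean and
sd vectors parameterize a diagonal-covariance Gaussian — nothing in the
parameterization specifies cross-run covariance).

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `shift` (s) | 1.8 | per-run observed sd | distance of the down-shift Gaussian below the run mean |
| `width` (w) | 0.3 | per-run observed sd | spread of the down-shift Gaussian |
| `alpha_when_finite` | 0.8 | — | MAR weight for finite-EBM peptides; MNAR weight is its complement, and the roles swap for non-finite EBM |
| `rank` | auto | — | 2 when n < 20 runs; otherwise the effective rank of a provisionally completed matrix, rounded half-to-even and clipped to [2, min(m, n) − 1] |
| `lam` (λ) | 0.1 | squared log2 units | ridge shrinkage of the ALS solves; the rank is controlled primarily by the explicit `rank`, so λ is kept small for numerical stability rather than used as the rank-selection device |
| `tol` / `max_iter` | 1e-5 / 100 | — | convergence is declared when the relative objective change falls below `tol`; hitting `max_iter` returns the model with `converged=False` and a warning, not an exception |
| `min_observed` | 4 | observations | peptides with fewer observed values cannot be meaningfully constrained by a rank-2 model and are discarded before fitting |
| `small_study_threshold` | 20 | runs | boundary of the fixed-rank-2 regime |

The fixed 0.8/0.2 weights are deliberately not adaptive; `alpha_when_finite`
is exposed (including the boundary values 0 and 1, which degenerate to the
pure down-shift and pure low-rank imputers) for sensitivity analyses.

## Numerical choices

* **ALS updates.** With `A = UD` (U orthonormal), the B-subproblem is a
  multiresponse ridge regression with closed form
  `B̃ᵀ = (D² + λI)⁻¹DUᵀX*`; the factor pair is then re-orthogonalized via
  the SVD of `B̃D`, absorbing the rotation into U so the product `ABᵀ` is
  unchanged. The A-step is symmetric. `X*` is the observed data with
  missing entries filled at the current fit (the sparse-plus-low-rank
  filling scheme). Each half-step solves its subproblem exactly and the
  re-orthogonalization minimizes the penalty over factorizations with a
  fixed product, so the objective trace is non-increasing.
* **Initialization.** `U` from the QR decomposition of a seeded standard
  Gaussian matrix, `D = I`. Fits are bit-reproducible given the seed.
* **Pseudo-inverse limit.** Terms `d/(d² + λ)` are evaluated as 0 when
  both d and λ are 0, so rank-deficient iterates cannot divide by zero.
* **Effective rank on incomplete data.** The SVD needs a complete matrix;
  missing entries are provisionally filled with the peptide's observed
  mean (column means for a pathological fully missing row). This
  completion is used only for rank selection, never as an imputation.
  Which completion the erank "should" see is genuinely open; the
  row-mean fill is the least structured choice that preserves peptide
  level.
* **Quantile normalization.** Runs after imputation (the pipeline order
  is log2 → filter → impute → normalize). Ties within a column receive
  the mean of the reference values over the tied span, which keeps the
  transform idempotent and preserves the grand mean to 1e-9. Whether
  normalization statistics should instead be computed from observed
  entries only, before imputation, is not settled; a `--normalize before`
  mode (interpolated observed-quantile mapping) is provided without a
  claim that either order is correct.
* **Degenerate inputs.** A run whose observed values are constant
  (σ̂ = 0) gets point-mass down-shift imputations at its mean. A run with
  fewer than 2 observed values is an error (no sample sd). Single-group
  designs are allowed: every peptide with at least one observation then
  has finite EBM and the pipeline degrades to α_MAR-weighted low-rank
  imputation.
* **Seeding.** The pipeline seed is split into independent child seeds
  for the ALS initialization and the down-shift draws via
  `SeedSequence.spawn`, so the two stages never share a stream.

## Synthetic data generator

The generator emulates the data model the method assumes: peptide
baselines `~ N(20, 2²)` on the log2 scale, iid measurement noise
`N(0, 0.5²)`, optional ± effect-size shifts for a differential subset in
the second group, and three disjoint missingness layers — uniform MAR
masking; intensity-dependent left-censoring with a logistic curve
`P(miss | x) = 1/(1 + exp((x − q)/τ))` centred on a quantile q of the
complete matrix (τ = 0.3 by default; the logistic form is the standard
simulation convention for detection-limit censoring); and whole-group
deletion for a subset of the down-regulated differential peptides, which
is the physically motivated group-specific pattern (down-regulation
pushes the whole group below the detection limit).

What the generator does **not** emulate: run-level batch effects,
correlated fractionation runs, and quantification-software artifacts such
as match-between-runs misidentification. Tests passing on this generator
therefore demonstrate correctness of the algorithm under its own data
model, not performance on any real dataset.

Validation experiments use desk-scale problem sizes chosen to keep the
whole suite fast while leaving the statistics well resolved: recovery
orderings on 1000 peptides × 12 runs over five seeds, and the null
p-value experiment on 2000 peptides × 10 technical replicates (≈ 15%
mixed missingness, random balanced split, per-peptide two-sample t-tests).
In the recovery and null comparisons the "pure low-rank" and "pure
down-shift" arms reuse the fits and draws of the barycenter run (common
random numbers), so differences between arms reflect the weighting rule,
not sampling noise. The down-shift calibration experiment uses a run with
observed sample mean 20 and sd exactly 1 plus 100,000 missing entries, so
the empirical shift and width of the draws estimate s and w directly.

Differential-abundance scoring in `recovery_metrics` uses ordinary
two-sample t-tests with Benjamini–Hochberg control. This is deliberately
plain test plumbing: it ranks methods, but absolute TP/FP counts are not
comparable to analyses that use moderated (empirical-Bayes) statistics.

## Known limitations

* The barycenter is computed entry-wise; no distributional
  (optimal-transport) interpolation is attempted.
* The weights are fixed, not estimated; datasets where the group-specific
  and random missingness populations overlap in abundance will benefit
  less from the classification.
* λ is not tuned; users fitting very noisy data at high rank may want to
  raise it.
* The evidence reader supports MaxQuant dialects only; other
  quantification tools' exports should be brought in as wide matrices.
* ALS convergence speed depends on the random initialization; on some
  inputs the default 100 iterations stop short of the tolerance (the
  model is still returned, flagged unconverged, and is typically within a
  fraction of a percent of the converged objective).
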