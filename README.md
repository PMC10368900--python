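# baryimpute

Missingness-aware imputation of peptide intensities in label-free
quantitative mass spectrometry (LFQ).

## The problem

LFQ experiments quantify thousands of peptides across a handful of LC-MS
runs, and a substantial fraction of the resulting peptide-by-run intensity
matrix is missing. The missing values are a mixture of two mechanisms:

* **MAR** (missing at random) — stochastic acquisition effects, unrelated
  to the underlying abundance;
* **MNAR** (missing not at random) — left-censoring of low-abundance
  peptides, often in a *group-specific* pattern (e.g. a protein
  down-regulated in one condition falls below the detection limit in all
  runs of that condition).

Imputing everything with a MAR-style method (low-rank completion, KNN,
...) overestimates censored values and over-smooths variances; imputing
everything with an MNAR-style method (down-shifted Gaussians) biases the
randomly missing entries low. `baryimpute` estimates each missing entry
under **both** assumptions and combines them.

## The method

For a log2 intensity matrix `X` (m peptides x n runs) with observed-entry
set Ω:

1. **MAR estimate** `X_MAR` — low-rank matrix completion by
   softImpute-ALS: find factors `A` (m x r) and `B` (n x r) minimizing
   `½‖P_Ω(X − ABᵀ)‖²_F + λ/2(‖A‖²_F + ‖B‖²_F)` by alternating closed-form
   ridge regressions with SVD re-orthogonalization. The rank `r` is 2 for
   studies with fewer than 20 runs, otherwise the rounded *effective rank*
   `erank(X) = exp(−Σ p_k log p_k)` of the normalized singular-value
   distribution `p_k = ξ_k/‖ξ‖₁`.
2. **MNAR estimate** `X_MNAR` — the down-shift approach: each missing
   entry in run k is a draw from `N(x̄_k − s·σ̂_k, (w·σ̂_k)²)` with
   defaults `s = 1.8`, `w = 0.3`, where `x̄_k`, `σ̂_k` are the mean and
   sample sd of the run's observed values.
3. **Entropy of mixing** — for each peptide i, with `m_ig` the proportion
   of observed values in group g, `EBM_i = Σ_g m_ig log m_ig`. `EBM` is
   finite iff the peptide is observed at least once in every group;
   a non-finite `EBM` flags group-specific (MNAR-like) missingness.
4. **Barycenter** — under squared-Euclidean distance the barycenter of the
   two estimates with weights `α_MAR + α_MNAR = 1` is the weighted
   average, so each missing entry becomes
   `X′_ik = α_i^MAR·X_MAR_ik + α_i^MNAR·X_MNAR_ik`,
   with fixed weights `α_i^MAR = 0.8` if `EBM_i` is finite and `0.2`
   otherwise.

Preprocessing follows the standard LFQ order: collapse MaxQuant evidence
features to peptide level (max intensity per peptide/run, contaminants and
reverse hits removed), log2-transform, discard peptides with too few
observations (default: fewer than 4), impute, quantile-normalize.

## Worked example

```python
import baryimpute as bi

# a synthetic 1000 x 12 two-group dataset with known truth: 20% of
# peptides differential (|effect| = 4), half of those fully censored in
# the down-regulated group, plus 10% uniform MAR masking
x, truth = bi.simulate_dataset(
    m=1000, runs_per_group=[6, 6], de_fraction=0.2, effect_size=4.0,
    group_deletion_fraction=0.5, mar_fraction=0.1, seed=11,
)
xf, removed = bi.filter_min_observed(x, 4)
res = bi.barycenter_impute(xf, truth.design, bi.ImputeConfig(seed=11))
metrics = bi.recovery_metrics(truth, res)
```

which prints (via the obvious `print` statements):

```
peptides kept: 997 (removed 3)
rank used: 2
mv_type counts: {'random': 619, 'complete': 281, 'group_specific': 97}
rmse_overall: 2.140
rmse_mar: 1.343
rmse_mnar_group: 3.125
pearson_overall: 0.859
da_tp: 197
da_fp: 11
da_fn: 0
```

The 12-run study gets a rank-2 model; 97 peptides are flagged
group-specific by the EBM rule (the 100 group-deleted ones minus 3 that
fell below the observation filter). Imputation error is smallest for the
randomly missing entries, which the low-rank model reconstructs well, and
larger for the censored group (where only the down-shifted draws carry
information). A per-peptide t-test with Benjamini–Hochberg control at 5%
FDR then recovers all 197 surviving differential peptides with 11 false
positives.

The same pipeline is available from the shell:

```sh
baryimpute simulate --m 1000 --runs-per-group 6,6 --seed 11 --out-dir sim/
baryimpute impute --input sim/simulated_matrix.tsv --groups sim/design.tsv \
    --no-log2 --seed 11 --out-dir out/
baryimpute diagnose --input sim/simulated_matrix.tsv --groups sim/design.tsv
```

`impute` writes the completed matrix, a per-peptide annotation table
(EBM, missingness class, weights, per-group observed fractions) and a
provenance JSON sufficient to reproduce the run byte-for-byte.

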