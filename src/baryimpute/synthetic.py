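"""Synthetic LFQ-like data with known truth, and recovery metrics.

The generator emulates a log2-scale peptide-by-run intensity matrix with
group structure and three missingness mechanisms, each recorded in its own
mask so recovery can be scored per mechanism:

* **MAR** — uniform Bernoulli masking, independent of intensity;
* **intensity-dependent MNAR** — left-censoring with a logistic
  probability curve P(miss | value) = 1 / (1 + exp((value - q) / tau))
  centred on a chosen quantile q of the complete matrix;
* **group-specific MNAR** — all runs of one group deleted for a subset of
  down-regulated differential peptides, the pattern the entropy-of-mixing
  classifier is designed to catch.

Peptide baselines are Gaussian, which matches how log-scale protein
abundance is conventionally modelled; what the generator does not emulate
are quantification artifacts of real pipelines (e.g. match-between-runs
misidentification), so results on it bound idealized behaviour only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .barycenter import ImputationResult
from .core import GroupDesign, IntensityMatrix

__all__ = [
    "SimulationTruth",
    "simulate_dataset",
    "simulate_null_replicates",
    "recovery_metrics",
    "rmse_at",
    "two_group_ttest_pvalues",
    "write_simulation",
]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset.

    The three masks are pairwise disjoint and cover exactly the missing
    entries of the released matrix.
    """

    complete_matrix: np.ndarray          # (m, n), log2 scale, finite
    group_effects: np.ndarray            # (m, G) per-peptide per-group shifts
    mar_mask: np.ndarray                 # uniform-random missing
    mnar_intensity_mask: np.ndarray      # left-censored missing
    mnar_group_mask: np.ndarray          # whole-group deletions
    de_labels: np.ndarray                # (m,) bool, truly differential
    design: GroupDesign
    peptide_ids: list[str]
    run_ids: list[str]
    params: dict = field(default_factory=dict)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.mar_mask | self.mnar_intensity_mask | self.mnar_group_mask


def _make_design(runs_per_group: list[int]) -> tuple[GroupDesign, list[str]]:
    groups = [chr(ord("A") + i) for i in range(len(runs_per_group))]
    run_ids: list[str] = []
    assignment: dict[str, str] = {}
    for g, k in zip(groups, runs_per_group):
        for j in range(k):
            rid = f"{g}{j + 1}"
            run_ids.append(rid)
            assignment[rid] = g
    return GroupDesign(assignment, groups), run_ids


def simulate_dataset(
    m: int,
    runs_per_group: list[int],
    base_mean: float = 20.0,
    peptide_sd: float = 2.0,
    noise_sd: float = 0.5,
    de_fraction: float = 0.1,
    effect_size: float = 2.0,
    mar_fraction: float = 0.1,
    mnar_censor_quantile: float = 0.0,
    group_deletion_fraction: float = 0.0,
    censor_scale: float = 0.3,
    seed: int = 0,
) -> tuple[IntensityMatrix, SimulationTruth]:
    """Simulate a log2 intensity matrix with controllable missingness.

    Peptide baselines are Normal(base_mean, peptide_sd^2); a ``de_fraction``
    subset receives a +/- ``effect_size`` shift in the second group;
    measurement noise is iid Normal(0, noise_sd^2).  Missingness is applied
    in three disjoint layers: whole-group deletion of a
    ``group_deletion_fraction`` subset of the down-regulated differential
    peptides, uniform MAR masking at rate ``mar_fraction``, and logistic
    left-censoring around the ``mnar_censor_quantile`` of the complete
    matrix (skipped when the quantile is 0).  Fully reproducible from seed.
    """
    for name, val in (
        ("de_fraction", de_fraction), ("mar_fraction", mar_fraction),
        ("mnar_censor_quantile", mnar_censor_quantile),
        ("group_deletion_fraction", group_deletion_fraction),
    ):
        if not 0.0 <= val <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    if mar_fraction > 0.5:
        raise ValueError("mar_fraction > 0.5 leaves too few observations")
    if de_fraction > 0 and len(runs_per_group) < 2:
        raise ValueError("differential simulation needs >= 2 groups")

    rng = np.random.default_rng(seed)
    design, run_ids = _make_design(list(runs_per_group))
    G = design.n_groups
    n = len(run_ids)
    peptide_ids = [f"PEP{i + 1:05d}" for i in range(m)]

    baseline = rng.normal(base_mean, peptide_sd, size=m)
    group_effects = np.zeros((m, G))
    n_de = int(round(de_fraction * m))
    de_idx = rng.choice(m, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)

    # whole-group deletions target down-regulated differential peptides:
    # their true values in the deleted group sit in the left tail, which is
    # what group-specific censoring means physically
    n_del = int(round(group_deletion_fraction * n_de))
    del_idx = de_idx[:n_del]
    signs[:n_del] = -1.0
    if n_de:
        group_effects[de_idx, 1] = signs * effect_size

    group_of_col = np.array([design.groups.index(design.assignment[r]) for r in run_ids])
    complete = (
        baseline[:, None]
        + group_effects[:, group_of_col]
        + rng.normal(0.0, noise_sd, size=(m, n))
    )

    mnar_group_mask = np.zeros((m, n), dtype=bool)
    if n_del:
        cols_b = group_of_col == 1
        mnar_group_mask[np.ix_(del_idx, np.flatnonzero(cols_b))] = True

    mar_mask = (rng.random((m, n)) < mar_fraction) & ~mnar_group_mask

    mnar_intensity_mask = np.zeros((m, n), dtype=bool)
    if mnar_censor_quantile > 0:
        q = np.quantile(complete, mnar_censor_quantile)
        p_miss = 1.0 / (1.0 + np.exp((complete - q) / censor_scale))
        mnar_intensity_mask = (
            (rng.random((m, n)) < p_miss) & ~mnar_group_mask & ~mar_mask
        )

    missing = mar_mask | mnar_intensity_mask | mnar_group_mask
    observed_per_row = (~missing).sum(axis=1)
    # individual fully-censored peptides are realistic (entirely below the
    # detection limit) and are removed downstream by observation filtering;
    # the parameters are infeasible only when they cripple most of the data
    if np.median(observed_per_row) < 2:
        raise ValueError(
            "infeasible missingness parameters: the majority of peptides "
            "retain fewer than 2 observations"
        )

    values = np.where(missing, np.nan, complete)
    x = IntensityMatrix(values, ~missing, peptide_ids, run_ids)
    de_labels = np.zeros(m, dtype=bool)
    de_labels[de_idx] = True
    truth = SimulationTruth(
        complete_matrix=complete,
        group_effects=group_effects,
        mar_mask=mar_mask,
        mnar_intensity_mask=mnar_intensity_mask,
        mnar_group_mask=mnar_group_mask,
        de_labels=de_labels,
        design=design,
        peptide_ids=peptide_ids,
        run_ids=run_ids,
        params=dict(
            m=m, runs_per_group=list(runs_per_group), base_mean=base_mean,
            peptide_sd=peptide_sd, noise_sd=noise_sd, de_fraction=de_fraction,
            effect_size=effect_size, mar_fraction=mar_fraction,
            mnar_censor_quantile=mnar_censor_quantile,
            group_deletion_fraction=group_deletion_fraction,
            censor_scale=censor_scale, seed=seed,
        ),
    )
    return x, truth


def simulate_null_replicates(
    m: int,
    n: int = 10,
    mar_fraction: float = 0.1,
    mnar_censor_quantile: float = 0.1,
    seed: int = 0,
) -> tuple[IntensityMatrix, SimulationTruth]:
    """Technical replicates with no group structure (null experiment).

    All runs form a single condition and every group effect is exactly
    zero; missingness mixes uniform MAR masking with intensity-dependent
    left-censoring.  Splitting the runs into two arbitrary halves and
    testing per peptide should then yield uniform p-values.
    """
    if n % 2:
        raise ValueError("n must be even for a balanced null split")
    return simulate_dataset(
        m=m, runs_per_group=[n], de_fraction=0.0, effect_size=0.0,
        mar_fraction=mar_fraction, mnar_censor_quantile=mnar_censor_quantile,
        group_deletion_fraction=0.0, seed=seed,
    )


def rmse_at(truth_matrix: np.ndarray, estimate: np.ndarray, mask: np.ndarray) -> float:
    """Root-mean-square error between two matrices over masked entries."""
    if not mask.any():
        return float("nan")
    diff = (estimate - truth_matrix)[mask]
    return float(np.sqrt(np.mean(diff ** 2)))


def two_group_ttest_pvalues(
    values: np.ndarray, run_ids: list[str], design: GroupDesign
) -> np.ndarray:
    """Per-peptide Welch-free two-sample t-test p-values, first two groups."""
    idx = design.group_indices(run_ids)
    if len(idx) < 2:
        raise ValueError("two groups are required for a two-sample test")
    g1, g2 = (idx[g] for g in design.groups[:2])
    res = stats.ttest_ind(values[:, g1], values[:, g2], axis=1)
    return np.asarray(res.pvalue)


def recovery_metrics(
    truth: SimulationTruth, result: ImputationResult, fdr: float = 0.05
) -> dict:
    """Score an imputation against simulation truth.

    Reports RMSE and Pearson correlation of imputed vs true values at the
    missing entries, overall and stratified by mechanism, plus a
    differential-abundance evaluation (per-peptide two-sample t-tests with
    Benjamini-Hochberg control) against the true differential labels when
    the design has two or more groups.
    """
    # align on the peptides that survived preprocessing
    pos = {p: i for i, p in enumerate(truth.peptide_ids)}
    rows = np.array([pos[p] for p in result.peptide_ids])
    if list(truth.run_ids) != list(result.run_ids):
        raise ValueError("run ids of truth and result differ")

    complete = truth.complete_matrix[rows]
    masks = {
        "overall": truth.missing_mask[rows],
        "mar": truth.mar_mask[rows],
        "mnar_intensity": truth.mnar_intensity_mask[rows],
        "mnar_group": truth.mnar_group_mask[rows],
    }
    out: dict = {}
    for name, mask in masks.items():
        out[f"rmse_{name}"] = rmse_at(complete, result.completed, mask)
        if mask.sum() >= 2:
            r = stats.pearsonr(complete[mask], result.completed[mask]).statistic
            out[f"pearson_{name}"] = float(r)
        else:
            out[f"pearson_{name}"] = float("nan")
        out[f"n_{name}"] = int(mask.sum())

    if truth.design.n_groups >= 2:
        from statsmodels.stats.multitest import multipletests

        pvals = two_group_ttest_pvalues(result.completed, result.run_ids, truth.design)
        ok = np.isfinite(pvals)
        reject = np.zeros_like(pvals, dtype=bool)
        if ok.any():
            reject[ok] = multipletests(pvals[ok], alpha=fdr, method="fdr_bh")[0]
        de = truth.de_labels[rows]
        out["da_tp"] = int((reject & de).sum())
        out["da_fp"] = int((reject & ~de).sum())
        out["da_fn"] = int((~reject & de).sum())
        out["fdr_level"] = fdr
    return out


def write_simulation(
    x: IntensityMatrix, truth: SimulationTruth, out_dir: str
) -> dict[str, str]:
    """Write a simulated dataset: matrix, design, truth tables, params."""
    import json
    import os

    from .core import write_wide_matrix

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "simulated_matrix.tsv"),
        "design": os.path.join(out_dir, "design.tsv"),
        "truth": os.path.join(out_dir, "truth_complete.tsv"),
        "masks": os.path.join(out_dir, "truth_masks.tsv"),
        "params": os.path.join(out_dir, "params.json"),
    }
    write_wide_matrix(x, paths["matrix"])
    pd.DataFrame({
        "run_id": x.run_ids,
        "group": [truth.design.assignment[r] for r in x.run_ids],
    }).to_csv(paths["design"], sep="\t", index=False)
    complete = IntensityMatrix(
        truth.complete_matrix, np.ones_like(truth.mar_mask),
        truth.peptide_ids, truth.run_ids,
    )
    write_wide_matrix(complete, paths["truth"])
    long = []
    for name, mask in (
        ("mar", truth.mar_mask),
        ("mnar_intensity", truth.mnar_intensity_mask),
        ("mnar_group", truth.mnar_group_mask),
    ):
        ii, jj = np.nonzero(mask)
        for i, j in zip(ii, jj):
            long.append((truth.peptide_ids[i], truth.run_ids[j], name))
    pd.DataFrame(long, columns=["peptide_id", "run_id", "mechanism"]).to_csv(
        paths["masks"], sep="\t", index=False
    )
    with open(paths["params"], "w") as fh:
        json.dump(truth.params, fh, indent=2)
    return paths
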