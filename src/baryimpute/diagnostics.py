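"""Post-imputation quality tables.

Imputation should neither over-smooth the data (deflating the coefficient
of variation of low-abundance peptides) nor inject spurious variability.
The mean vs squared-CV table computed before (observed entries only) and
after imputation makes both failure modes visible; an optional
locally-weighted trend supports plotting.  The missingness summary reports
per-run missing fractions and the composition of missingness classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .barycenter import ImputationResult, classify_missingness
from .core import GroupDesign, IntensityMatrix

__all__ = ["mean_cv_table", "loess_trend", "missingness_summary"]


def _row_mean_cv2(values: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean and squared CV (sample sd / mean)^2 over masked entries.

    Rows with fewer than 2 usable entries or zero mean get NaN CV^2.
    """
    m = values.shape[0]
    means = np.full(m, np.nan)
    cv2 = np.full(m, np.nan)
    for i in range(m):
        obs = values[i, mask[i]]
        if obs.size == 0:
            continue
        mu = obs.mean()
        means[i] = mu
        if obs.size >= 2 and mu != 0:
            cv2[i] = (obs.std(ddof=1) / mu) ** 2
    return means, cv2


def mean_cv_table(
    x: IntensityMatrix,
    result: ImputationResult,
    scale: str = "log2",
) -> pd.DataFrame:
    """Per-peptide mean abundance and squared CV, pre and post imputation.

    Statistics are computed on the log2-scale values by default (matching
    the scale the pipeline operates on); ``scale="linear"`` exponentiates
    first.  Pre-imputation columns use observed entries only.
    """
    if scale not in ("log2", "linear"):
        raise ValueError("scale must be 'log2' or 'linear'")
    if x.shape != result.completed.shape:
        raise ValueError("matrix and imputation result shapes differ")

    pre_vals = x.values if scale == "log2" else np.power(2.0, x.values)
    post_vals = result.completed if scale == "log2" else np.power(2.0, result.completed)
    full = np.ones_like(x.mask)

    mean_obs, cv2_obs = _row_mean_cv2(pre_vals, x.mask)
    mean_post, cv2_post = _row_mean_cv2(post_vals, full)

    table = pd.DataFrame({
        "peptide_id": x.peptide_ids,
        "mean_observed": mean_obs,
        "cv2_observed": cv2_obs,
        "mean_imputed": mean_post,
        "cv2_imputed": cv2_post,
    })
    ann = result.annotations.set_index("peptide_id")
    table["ebm"] = ann["ebm"].reindex(table["peptide_id"]).to_numpy()
    table["mv_type"] = ann["mv_type"].reindex(table["peptide_id"]).to_numpy()
    return table


def loess_trend(
    mean: np.ndarray, cv2: np.ndarray, frac: float = 0.75
) -> pd.DataFrame:
    """Locally weighted trend of CV^2 against mean abundance (for plotting)."""
    from statsmodels.nonparametric.smoothers_lowess import lowess

    ok = np.isfinite(mean) & np.isfinite(cv2)
    fitted = lowess(cv2[ok], mean[ok], frac=frac, return_sorted=True)
    return pd.DataFrame({"mean": fitted[:, 0], "cv2_trend": fitted[:, 1]})


def missingness_summary(
    x: IntensityMatrix, design: GroupDesign
) -> dict[str, pd.DataFrame]:
    """Per-run missing fractions plus missingness-class composition.

    Returns three tables: ``runs`` (missing fraction per run), ``types``
    (peptide counts per missingness class) and ``abundance`` (long table of
    per-peptide mean observed abundance by class, ready for violin plots).
    """
    design.validate_runs(x.run_ids)
    runs = pd.DataFrame({
        "run_id": x.run_ids,
        "group": [design.assignment[r] for r in x.run_ids],
        "missing_fraction": (~x.mask).mean(axis=0),
        "n_observed": x.mask.sum(axis=0),
    })

    missingness = classify_missingness(x, design)
    types = (
        pd.Series([p.mv_type for p in missingness])
        .value_counts()
        .rename_axis("mv_type")
        .reset_index(name="n_peptides")
    )

    mean_obs, _ = _row_mean_cv2(x.values, x.mask)
    abundance = pd.DataFrame({
        "peptide_id": x.peptide_ids,
        "mv_type": [p.mv_type for p in missingness],
        "mean_observed": mean_obs,
        "ebm": [p.ebm for p in missingness],
    })
    return {"runs": runs, "types": types, "abundance": abundance}
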