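"""Entropy-based missingness classification and barycentric imputation.

Each peptide's missing entries are estimated twice — once under a
missing-at-random model (low-rank reconstruction) and once under a
group-specific missing-not-at-random model (down-shifted Gaussian draws) —
and the final value is the barycenter of the two estimates.  Under squared
Euclidean distance the barycenter of two distributions with weights summing
to one is simply their weighted average, so the imputed entry is the convex
combination

    x'_ik = alpha_MAR * x_MAR_ik + alpha_MNAR * x_MNAR_ik.

The weights come from the entropy of mixing (EBM) of the peptide's
observed-value pattern across experimental groups:

    EBM_i = sum_g m_ig * ln(m_ig),

with m_ig the proportion of observed values in group g.  If a peptide is
entirely missing in some group, EBM is -infinity — evidence of
group-specific (MNAR) missingness — and the down-shift estimate dominates
(alpha_MNAR = 0.8).  A finite EBM signals evenly spread (MAR-like)
missingness and the low-rank estimate dominates (alpha_MAR = 0.8).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import GroupDesign, IntensityMatrix
from .downshift import DownshiftParams, downshift_impute
from .lowrank import reconstruct, select_rank, softimpute_als

__all__ = [
    "MV_COMPLETE",
    "MV_RANDOM",
    "MV_GROUP_SPECIFIC",
    "ImputeConfig",
    "PeptideMissingness",
    "ImputationResult",
    "entropy_of_mixing",
    "assign_weights",
    "classify_missingness",
    "barycenter_impute",
    "write_result",
]

MV_COMPLETE = "complete"
MV_RANDOM = "random"
MV_GROUP_SPECIFIC = "group_specific"


@dataclass
class ImputeConfig:
    """Tunable parameters of the full imputation pipeline.

    rank 0 means automatic selection (rank 2 below ``small_study_threshold``
    runs, rounded effective rank otherwise).
    """

    rank: int = 0
    lam: float = 0.1
    tol: float = 1e-5
    max_iter: int = 100
    shift: float = 1.8
    width: float = 0.3
    alpha_when_finite: float = 0.8
    small_study_threshold: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_when_finite <= 1.0:
            raise ValueError("alpha_when_finite must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class PeptideMissingness:
    """Per-peptide EBM value, missingness class and barycenter weights."""

    ebm: float                       # finite <= 0, or -inf
    mv_type: str                     # complete | random | group_specific
    alpha_mar: float
    alpha_mnar: float
    observed_fraction_per_group: np.ndarray


@dataclass
class ImputationResult:
    """Completed matrix plus per-peptide annotations and provenance."""

    completed: np.ndarray
    annotations: pd.DataFrame
    mar_estimate: np.ndarray
    mnar_estimate: np.ndarray
    provenance: dict = field(default_factory=dict)
    peptide_ids: list[str] = field(default_factory=list)
    run_ids: list[str] = field(default_factory=list)

    def to_matrix(self) -> IntensityMatrix:
        """The completed matrix as a fully observed IntensityMatrix."""
        return IntensityMatrix(
            self.completed, np.ones_like(self.completed, dtype=bool),
            list(self.peptide_ids), list(self.run_ids),
        )


def entropy_of_mixing(mask_row: Sequence[bool] | np.ndarray, design: GroupDesign,
                      run_ids: list[str]) -> float:
    """EBM of one peptide: sum over groups of m_g * ln(m_g).

    m_g is the proportion of observed values in group g.  Returns -inf when
    any group is fully missing (group-specific pattern); otherwise a finite
    value <= 0, equal to 0 only for a fully observed peptide.
    """
    mask_row = np.asarray(mask_row, dtype=bool)
    total = 0.0
    for idx in design.group_indices(run_ids).values():
        frac = float(mask_row[idx].mean())
        if frac == 0.0:
            return float("-inf")
        total += frac * np.log(frac)
    return total


def assign_weights(ebm: float, alpha_when_finite: float = 0.8) -> tuple[float, float]:
    """(alpha_MAR, alpha_MNAR) from the EBM finiteness rule.

    Finite EBM -> (alpha_when_finite, 1 - alpha_when_finite); -inf ->
    the reverse.  The weights always sum to one exactly.
    """
    if not 0.0 <= alpha_when_finite <= 1.0:
        raise ValueError("alpha_when_finite must be in [0, 1]")
    if np.isfinite(ebm):
        return alpha_when_finite, 1.0 - alpha_when_finite
    return 1.0 - alpha_when_finite, alpha_when_finite


def classify_missingness(
    x: IntensityMatrix, design: GroupDesign, alpha_when_finite: float = 0.8
) -> list[PeptideMissingness]:
    """EBM, missingness class and weights for every peptide."""
    design.validate_runs(x.run_ids)
    group_idx = design.group_indices(x.run_ids)
    out: list[PeptideMissingness] = []
    for i in range(x.shape[0]):
        row = x.mask[i]
        fracs = np.array([row[idx].mean() for idx in group_idx.values()])
        if (fracs == 0.0).any():
            ebm = float("-inf")
        else:
            ebm = float((fracs * np.log(fracs)).sum())
        a_mar, a_mnar = assign_weights(ebm, alpha_when_finite)
        if row.all():
            mv = MV_COMPLETE
        elif np.isfinite(ebm):
            mv = MV_RANDOM
        else:
            mv = MV_GROUP_SPECIFIC
        out.append(PeptideMissingness(ebm, mv, a_mar, a_mnar, fracs))
    return out


def barycenter_impute(
    x: IntensityMatrix,
    design: GroupDesign,
    config: ImputeConfig | None = None,
) -> ImputationResult:
    """Run the full pipeline: low-rank fit, down-shift, EBM-weighted combine.

    The input must already be log2-scaled and filtered so every peptide has
    enough observations to constrain the low-rank model.  Observed entries
    pass through unchanged; each missing entry becomes the per-peptide
    convex combination of the low-rank and down-shift estimates.
    Deterministic given ``config.seed``.
    """
    if config is None:
        config = ImputeConfig()
    design.validate_runs(x.run_ids)

    # independent child seeds for the two stochastic stages
    ss = np.random.SeedSequence(config.seed)
    seed_als, seed_ds = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))

    rank = config.rank if config.rank > 0 else select_rank(
        x, config.small_study_threshold
    )
    model = softimpute_als(
        x, rank=rank, lam=config.lam, tol=config.tol,
        max_iter=config.max_iter, seed=seed_als,
    )
    x_mar = reconstruct(model)
    x_mnar = downshift_impute(
        x, DownshiftParams(shift=config.shift, width=config.width, seed=seed_ds)
    )

    missingness = classify_missingness(x, design, config.alpha_when_finite)
    alpha_mar = np.array([p.alpha_mar for p in missingness])[:, None]
    alpha_mnar = np.array([p.alpha_mnar for p in missingness])[:, None]
    combined = alpha_mar * x_mar + alpha_mnar * x_mnar
    completed = np.where(x.mask, x.values, combined)

    annotations = pd.DataFrame({
        "peptide_id": x.peptide_ids,
        "ebm": [p.ebm for p in missingness],
        "mv_type": [p.mv_type for p in missingness],
        "alpha_mar": [p.alpha_mar for p in missingness],
        "alpha_mnar": [p.alpha_mnar for p in missingness],
        "n_observed": x.n_observed_per_peptide,
    })
    for gi, g in enumerate(design.groups):
        annotations[f"observed_fraction_{g}"] = [
            p.observed_fraction_per_group[gi] for p in missingness
        ]

    mad = float(np.abs((x.values - x_mar)[x.mask]).mean())
    provenance = {
        "software": "baryimpute",
        "version": __version__,
        "config": asdict(config),
        "rank_used": int(rank),
        "seed_als": seed_als,
        "seed_downshift": seed_ds,
        "n_peptides": int(x.shape[0]),
        "n_runs": int(x.shape[1]),
        "groups": list(design.groups),
        "n_missing": int((~x.mask).sum()),
        "lowrank_n_iter": model.n_iter,
        "lowrank_converged": model.converged,
        "lowrank_objective_trace": [float(v) for v in model.objective_trace],
        "lowrank_observed_mad": mad,
    }
    return ImputationResult(
        completed=completed,
        annotations=annotations,
        mar_estimate=x_mar,
        mnar_estimate=x_mnar,
        provenance=provenance,
        peptide_ids=list(x.peptide_ids),
        run_ids=list(x.run_ids),
    )


def write_result(result: ImputationResult, out_dir: str) -> dict[str, str]:
    """Write completed matrix, annotations and provenance to ``out_dir``."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "imputed_matrix.tsv"),
        "annotations": os.path.join(out_dir, "peptide_annotations.tsv"),
        "provenance": os.path.join(out_dir, "provenance.json"),
    }
    from .core import write_wide_matrix

    write_wide_matrix(result.to_matrix(), paths["matrix"])
    result.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    with open(paths["provenance"], "w") as fh:
        json.dump(result.provenance, fh, indent=2)
    return paths
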