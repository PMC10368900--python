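"""Low-rank reconstruction of intensities missing at random.

The matrix-completion engine is softImpute-ALS: alternating multiresponse
ridge regressions on two factors A (peptides x rank) and B (runs x rank)
minimizing

    1/2 ||P_Omega(X - A B^T)||_F^2 + lambda/2 (||A||_F^2 + ||B||_F^2)

where P_Omega keeps observed entries only.  Each half-step solves its ridge
subproblem in closed form and re-orthogonalizes the factors through an SVD,
so the objective is non-increasing.  Missing entries are carried at their
current fitted values between half-steps (the sparse-plus-low-rank filling
scheme).

The model rank is chosen by the *effective rank*: exp of the Shannon entropy
of the normalized singular-value distribution, a continuous surrogate for
matrix rank.  Experiments with fewer than 20 LC-MS runs get a fixed rank-2
model, which approximates small studies better than the effective-rank
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import IntensityMatrix

__all__ = [
    "LowRankModel",
    "effective_rank",
    "provisional_completion",
    "select_rank",
    "softimpute_als",
    "ridge_b_update",
    "ridge_a_update",
    "reconstruct",
    "objective",
]


@dataclass
class LowRankModel:
    """Fitted factor pair with its shrinkage and convergence record."""

    A: np.ndarray                    # (m, rank) peptide factor
    B: np.ndarray                    # (n, rank) run factor
    lam: float                       # ridge shrinkage lambda
    rank: int
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def effective_rank(x: np.ndarray) -> float:
    """exp(Shannon entropy) of the normalized singular-value distribution.

    With singular values xi_k and p_k = xi_k / sum(xi), returns
    exp(-sum p_k ln p_k); zero singular values contribute nothing to the
    entropy.  Lies in [1, min(m, n)].
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("effective rank requires a complete, finite matrix")
    sv = np.linalg.svd(x, compute_uv=False)
    total = sv.sum()
    if total == 0:
        raise ValueError("undefined singular-value distribution (all-zero matrix)")
    p = sv / total
    nz = p > 0
    entropy = float(-(p[nz] * np.log(p[nz])).sum())
    return float(np.exp(entropy))


def provisional_completion(x: IntensityMatrix) -> np.ndarray:
    """Fill missing entries with the peptide's observed mean.

    Used only to obtain a complete matrix for the effective-rank estimate;
    a peptide with no observed values falls back to its runs' column means.
    """
    values = np.where(x.mask, x.values, np.nan)
    row_mean = np.nanmean(np.where(x.mask, x.values, np.nan), axis=1)
    col_counts = x.mask.sum(axis=0)
    if (col_counts == 0).any():
        raise ValueError("a run with no observed entries cannot be completed")
    col_mean = np.nansum(np.where(x.mask, x.values, 0.0), axis=0) / col_counts
    fill = np.where(np.isfinite(row_mean), row_mean, np.nan)[:, None]
    fill = np.broadcast_to(fill, x.shape).copy()
    bad_rows = ~np.isfinite(row_mean)
    if bad_rows.any():
        fill[bad_rows] = col_mean[None, :]
    return np.where(x.mask, values, fill)


def select_rank(x: IntensityMatrix, small_study_threshold: int = 20) -> int:
    """Model rank: 2 for small studies, rounded effective rank otherwise.

    Studies with fewer than ``small_study_threshold`` runs always get rank 2.
    Otherwise the effective rank of a provisionally completed matrix is
    rounded (half to even) and clipped to [2, min(m, n) - 1].
    """
    m, n = x.shape
    if n < small_study_threshold:
        return 2
    er = effective_rank(provisional_completion(x))
    r = int(round(er))
    return int(np.clip(r, 2, min(m, n) - 1))


def _shrunk_d(d: np.ndarray, lam: float) -> np.ndarray:
    """d / (d^2 + lam), with the pseudo-inverse limit 0 at d = 0, lam = 0."""
    denom = d * d + lam
    return np.divide(d, denom, out=np.zeros_like(d), where=denom > 0)


def ridge_b_update(x_filled: np.ndarray, U: np.ndarray, D: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge solution for B given A = U D.

    Solves min_B ||X - A B^T||_F^2 + lam ||B||_F^2 with orthonormal U:
    B~^T = (D^2 + lam I)^{-1} D U^T X.
    """
    d = np.diag(D) if D.ndim == 2 else np.asarray(D)
    return x_filled.T @ U * _shrunk_d(d, lam)[None, :]


def ridge_a_update(x_filled: np.ndarray, V: np.ndarray, D: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge solution for A given B = V D: A~ = X V D (D^2+lam I)^{-1}."""
    d = np.diag(D) if D.ndim == 2 else np.asarray(D)
    return x_filled @ V * _shrunk_d(d, lam)[None, :]


def objective(model: LowRankModel, x: IntensityMatrix) -> float:
    """Penalized observed-entry squared loss of a fitted model."""
    resid = (x.values - model.A @ model.B.T)[x.mask]
    return float(
        0.5 * (resid ** 2).sum()
        + 0.5 * model.lam * ((model.A ** 2).sum() + (model.B ** 2).sum())
    )


def reconstruct(model: LowRankModel) -> np.ndarray:
    """The completed matrix A B^T."""
    return model.A @ model.B.T


def softimpute_als(
    x: IntensityMatrix,
    rank: int,
    lam: float = 0.1,
    tol: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
) -> LowRankModel:
    """Fit the low-rank model by alternating ridge regressions.

    A = U D starts from a random orthonormal U (QR of a seeded Gaussian
    matrix) with D = I.  Each iteration solves for B then A in closed form,
    re-orthogonalizing through an SVD after each solve; missing entries of X
    are carried at their current fitted values.  Stops when the relative
    change of the objective drops below ``tol``; if ``max_iter`` is reached
    first the model is returned with ``converged=False`` and a warning.
    """
    m, n = x.shape
    if not 1 <= rank <= min(m, n):
        raise ValueError(f"rank must be in [1, {min(m, n)}]")
    rng = np.random.default_rng(seed)
    U, _ = np.linalg.qr(rng.standard_normal((m, rank)))
    d = np.ones(rank)
    V = np.zeros((n, rank))

    values = np.where(x.mask, x.values, 0.0)
    mask = x.mask
    trace: list[float] = []
    converged = False
    n_iter = 0

    def current_fit() -> np.ndarray:
        # A B^T with A = U D, B = V D is U D^2 V^T
        return (U * d * d) @ V.T

    def current_objective() -> float:
        resid = (x.values - current_fit())[mask]
        pen = 0.5 * lam * ((d ** 2).sum() * 2)  # ||A||^2 + ||B||^2 with A=UD, B=VD
        return float(0.5 * (resid ** 2).sum() + pen)

    prev = None
    for n_iter in range(1, max_iter + 1):
        # fill missing entries at current fitted values
        x_filled = np.where(mask, values, current_fit())

        # B-step: ridge solve, then SVD re-orthogonalization.
        # A B~^T = U (B~ D)^T; SVD of B~ D keeps the product intact while
        # restoring orthonormal V and a diagonal D (U absorbs the rotation).
        B_tilde = ridge_b_update(x_filled, U, d, lam)
        Vt, d_sq, Rt = np.linalg.svd(B_tilde * d[None, :], full_matrices=False)
        d = np.sqrt(d_sq)
        V = Vt
        U = U @ Rt.T

        x_filled = np.where(mask, values, current_fit())

        # A-step, symmetric to the B-step
        A_tilde = ridge_a_update(x_filled, V, d, lam)
        Ut, d_sq, Rt = np.linalg.svd(A_tilde * d[None, :], full_matrices=False)
        d = np.sqrt(d_sq)
        U = Ut
        V = V @ Rt.T

        obj = current_objective()
        trace.append(obj)
        if prev is not None:
            rel = abs(prev - obj) / max(abs(prev), 1e-12)
            if rel < tol:
                converged = True
                break
        prev = obj

    if not converged:
        warnings.warn(
            f"softImpute-ALS did not converge in {max_iter} iterations "
            f"(last objective {trace[-1]:.6g})", stacklevel=2,
        )
    A = U * d
    B = V * d
    return LowRankModel(
        A=A, B=B, lam=lam, rank=rank,
        objective_trace=trace, n_iter=n_iter, converged=converged,
    )
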