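"""Domain containers, file readers and the preprocessing chain.

The central object is :class:`IntensityMatrix`: a peptide-by-run matrix of
log2 (or raw) intensities together with an explicit boolean mask of observed
entries.  Readers produce raw-scale matrices; the preprocessing functions
(:func:`log2_transform`, :func:`filter_min_observed`,
:func:`quantile_normalize`) operate on and return new matrices — nothing
mutates its input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "IntensityMatrix",
    "GroupDesign",
    "read_wide_matrix",
    "write_wide_matrix",
    "read_group_design",
    "read_maxquant_evidence",
    "log2_transform",
    "filter_min_observed",
    "quantile_normalize",
    "quantile_normalize_observed",
    "DEFAULT_MISSING_TOKENS",
]

#: Cell contents in wide tables that denote a missing measurement.  Zero is
#: included because common LFQ exports write 0 for "not quantified".
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "0"})


class InputError(ValueError):
    """Raised when an input file or design table is malformed."""


@dataclass
class IntensityMatrix:
    """Peptide-by-run intensity matrix with an observed-entry mask.

    Parameters
    ----------
    values
        ``(m, n)`` float array.  Entries where ``mask`` is False are
        undefined (stored as NaN by the readers).
    mask
        ``(m, n)`` boolean array; True marks an observed measurement.
    peptide_ids
        ``m`` unique peptide identifiers (row labels).
    run_ids
        ``n`` unique run identifiers (column labels).
    """

    values: np.ndarray
    mask: np.ndarray
    peptide_ids: list[str]
    run_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.peptide_ids = [str(p) for p in self.peptide_ids]
        self.run_ids = [str(r) for r in self.run_ids]
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have identical shape")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        m, n = self.values.shape
        if len(self.peptide_ids) != m or len(self.run_ids) != n:
            raise ValueError("label lengths do not match matrix shape")
        if n < 2:
            raise ValueError("at least 2 runs are required")
        if len(set(self.peptide_ids)) != m:
            raise ValueError("duplicate peptide ids")
        if len(set(self.run_ids)) != n:
            raise ValueError("duplicate run ids")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed entries must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed_per_peptide(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(), self.mask.copy(),
            list(self.peptide_ids), list(self.run_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        """Observed values as a DataFrame, NaN where missing."""
        vals = np.where(self.mask, self.values, np.nan)
        return pd.DataFrame(vals, index=self.peptide_ids, columns=self.run_ids)


@dataclass
class GroupDesign:
    """Assignment of LC-MS runs to experimental groups.

    ``assignment`` maps each run id to a group label; ``groups`` fixes the
    order in which per-group quantities (observed fractions, effects) are
    reported.
    """

    assignment: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.groups:
            seen: list[str] = []
            for g in self.assignment.values():
                if g not in seen:
                    seen.append(g)
            self.groups = seen
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group labels")
        missing = set(self.assignment.values()) - set(self.groups)
        if missing:
            raise ValueError(f"groups {sorted(missing)} not in group list")
        counts = {g: 0 for g in self.groups}
        for g in self.assignment.values():
            counts[g] += 1
        empty = [g for g, c in counts.items() if c == 0]
        if empty:
            raise ValueError(f"groups with no runs: {empty}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def validate_runs(self, run_ids: list[str]) -> None:
        """Check that every run of a matrix is assigned to a group."""
        unassigned = [r for r in run_ids if r not in self.assignment]
        if unassigned:
            raise InputError(
                f"design does not assign runs to groups: {unassigned}"
            )

    def group_indices(self, run_ids: list[str]) -> dict[str, np.ndarray]:
        """Column indices of each group, in matrix column order."""
        self.validate_runs(run_ids)
        out: dict[str, np.ndarray] = {}
        for g in self.groups:
            idx = [k for k, r in enumerate(run_ids) if self.assignment[r] == g]
            out[g] = np.asarray(idx, dtype=int)
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_sep(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_wide_matrix(
    path: str,
    missing_tokens: frozenset[str] | set[str] = DEFAULT_MISSING_TOKENS,
) -> IntensityMatrix:
    """Read a wide peptide-by-run table (first column = peptide id).

    Cells whose stripped text matches ``missing_tokens`` become masked;
    everything else must parse as a number.
    """
    df = pd.read_csv(path, sep=_infer_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 3:
        raise InputError("wide matrix needs a peptide-id column and >= 2 runs")
    peptide_ids = [str(p) for p in df.iloc[:, 0]]
    dupes = sorted({p for p in peptide_ids if peptide_ids.count(p) > 1})
    if dupes:
        raise InputError(f"duplicate peptide ids: {dupes}")
    run_ids = [str(c) for c in df.columns[1:]]
    m, n = len(peptide_ids), len(run_ids)
    values = np.full((m, n), np.nan)
    mask = np.zeros((m, n), dtype=bool)
    cells = df.iloc[:, 1:].to_numpy(dtype=object)
    tokens = {t.strip() for t in missing_tokens}
    for i in range(m):
        for j in range(n):
            text = str(cells[i, j]).strip()
            if text in tokens:
                continue
            try:
                values[i, j] = float(text)
            except ValueError as exc:
                raise InputError(
                    f"non-numeric cell at row '{peptide_ids[i]}', "
                    f"column '{run_ids[j]}': {text!r}"
                ) from exc
            mask[i, j] = True
    return IntensityMatrix(values, mask, peptide_ids, run_ids)


def write_wide_matrix(x: IntensityMatrix, path: str, missing_token: str = "NA") -> None:
    """Write a wide TSV/CSV; full float precision so read-back is exact."""
    sep = _infer_sep(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["peptide_id", *x.run_ids]) + "\n")
        for i, pid in enumerate(x.peptide_ids):
            cells = [
                repr(float(x.values[i, j])) if x.mask[i, j] else missing_token
                for j in range(len(x.run_ids))
            ]
            fh.write(sep.join([pid, *cells]) + "\n")


def read_group_design(path: str) -> GroupDesign:
    """Read a run-to-group table: header row, then run id and group columns."""
    df = pd.read_csv(path, sep=_infer_sep(path), dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise InputError("design table needs columns: run id, group label")
    assignment = {
        str(r).strip(): str(g).strip()
        for r, g in zip(df.iloc[:, 0], df.iloc[:, 1])
    }
    if len(assignment) != len(df):
        raise InputError("duplicate run ids in design table")
    return GroupDesign(assignment)


# MaxQuant column dialects, most recent first.
_SEQ_COLS = ("Modified sequence", "Sequence")
_RAW_COLS = ("Raw file",)
_INT_COLS = ("Intensity",)
_CONTAM_COLS = ("Potential contaminant", "Contaminant")
_REVERSE_COLS = ("Reverse",)


def _pick(columns: pd.Index, candidates: tuple[str, ...]) -> str | None:
    for c in candidates:
        if c in columns:
            return c
    return None


def _flagged(series: pd.Series) -> np.ndarray:
    text = series.astype(str).str.strip()
    return text.isin({"+", "1", "True", "true", "TRUE", "yes", "Yes"}).to_numpy()


def read_maxquant_evidence(path: str) -> IntensityMatrix:
    """Collapse a MaxQuant ``evidence.txt`` to a raw-scale peptide x run matrix.

    Rows flagged as contaminant or reverse are dropped.  Multiple ions
    (charge states, features) for the same peptide/run are collapsed by
    keeping the highest intensity.  Cells with no surviving evidence row are
    masked.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    seq_col = _pick(df.columns, _SEQ_COLS)
    raw_col = _pick(df.columns, _RAW_COLS)
    int_col = _pick(df.columns, _INT_COLS)
    missing = [
        name
        for name, col in (
            ("peptide sequence", seq_col),
            ("raw file", raw_col),
            ("intensity", int_col),
        )
        if col is None
    ]
    if missing:
        raise InputError(f"evidence table is missing required columns: {missing}")

    keep = np.ones(len(df), dtype=bool)
    for cands in (_CONTAM_COLS, _REVERSE_COLS):
        col = _pick(df.columns, cands)
        if col is not None:
            keep &= ~_flagged(df[col])
    df = df.loc[keep]

    intensities = pd.to_numeric(df[int_col].replace("", np.nan), errors="coerce")
    ok = intensities.notna() & (intensities > 0)
    df = df.loc[ok]
    intensities = intensities.loc[ok]

    if df.empty:
        raise InputError("no usable evidence rows after filtering")

    table = pd.DataFrame({
        "peptide": df[seq_col].to_numpy(),
        "run": df[raw_col].to_numpy(),
        "intensity": intensities.to_numpy(),
    })
    wide = table.pivot_table(
        index="peptide", columns="run", values="intensity", aggfunc="max"
    ).sort_index()
    values = wide.to_numpy(dtype=float)
    mask = ~np.isnan(values)
    return IntensityMatrix(
        values, mask, [str(p) for p in wide.index], [str(r) for r in wide.columns]
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def log2_transform(x: IntensityMatrix) -> IntensityMatrix:
    """log2 of every observed entry; the mask is unchanged.

    Raises if any observed entry is <= 0 (zeros should have been treated as
    missing by the reader).  Warns if the data already look log-scaled.
    """
    obs = x.values[x.mask]
    if obs.size and obs.min() <= 0:
        raise ValueError(
            "observed entries must be positive for log2 transform; "
            "treat zeros as missing values"
        )
    if obs.size and obs.max() < 64:
        warnings.warn(
            "max observed intensity < 64 — data may already be on the "
            "log2 scale", stacklevel=2,
        )
    values = x.values.copy()
    values[x.mask] = np.log2(obs)
    return IntensityMatrix(values, x.mask.copy(), list(x.peptide_ids), list(x.run_ids))


def filter_min_observed(
    x: IntensityMatrix, min_observed: int = 4
) -> tuple[IntensityMatrix, list[str]]:
    """Drop peptides observed in fewer than ``min_observed`` runs.

    Peptides with too few observations cannot be fitted reliably by the
    low-rank model and are discarded.  Returns the filtered matrix and the
    ids of the removed peptides, preserving input row order.
    """
    if min_observed < 1:
        raise ValueError("min_observed must be >= 1")
    keep = x.n_observed_per_peptide >= min_observed
    removed = [p for p, k in zip(x.peptide_ids, keep) if not k]
    if not keep.any():
        raise ValueError("no peptides survive filtering")
    out = IntensityMatrix(
        x.values[keep], x.mask[keep],
        [p for p, k in zip(x.peptide_ids, keep) if k], list(x.run_ids),
    )
    return out, removed


def quantile_normalize(x: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize a complete matrix.

    Every column's sorted values are replaced by the across-column mean of
    sorted values; ties within a column receive the mean of the reference
    values over their tied ranks.
    """
    if not x.is_complete:
        raise ValueError("quantile normalization requires a complete matrix")
    values = x.values
    m, n = values.shape
    sort_idx = np.argsort(values, axis=0, kind="stable")
    reference = np.take_along_axis(values, sort_idx, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n):
        order = sort_idx[:, j]
        col_sorted = values[order, j]
        assigned = reference.copy()
        # average the reference over runs of tied values
        start = 0
        for end in range(1, m + 1):
            if end == m or col_sorted[end] != col_sorted[start]:
                if end - start > 1:
                    assigned[start:end] = assigned[start:end].mean()
                start = end
        out[order, j] = assigned
    return IntensityMatrix(out, x.mask.copy(), list(x.peptide_ids), list(x.run_ids))


def quantile_normalize_observed(x: IntensityMatrix, grid: int = 1001) -> IntensityMatrix:
    """Quantile-normalize using observed entries only (incomplete matrices).

    Each column's observed values are mapped through a reference quantile
    function (the across-column mean of the per-column empirical quantile
    functions, evaluated on a common probability grid).  Used for the
    normalize-before-impute pipeline order; masked entries stay masked.
    """
    probs = np.linspace(0.0, 1.0, grid)
    qfuncs = []
    for j in range(x.shape[1]):
        obs = x.values[x.mask[:, j], j]
        if obs.size < 2:
            raise ValueError(f"run '{x.run_ids[j]}' has fewer than 2 observed entries")
        qfuncs.append(np.quantile(obs, probs))
    reference = np.mean(qfuncs, axis=0)
    values = x.values.copy()
    for j in range(x.shape[1]):
        sel = x.mask[:, j]
        obs = x.values[sel, j]
        # mid-ranks of each observed entry within its column
        order = np.argsort(np.argsort(obs, kind="stable"), kind="stable")
        ranks = (order + 0.5) / obs.size
        values[sel, j] = np.interp(ranks, probs, reference)
    return IntensityMatrix(values, x.mask.copy(), list(x.peptide_ids), list(x.run_ids))
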