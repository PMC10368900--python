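import numpy as np
import pytest

from baryimpute import GroupDesign, IntensityMatrix


@pytest.fixture
def two_group_design():
    """Six runs, two groups of three."""
    assignment = {f"A{i}": "A" for i in (1, 2, 3)}
    assignment.update({f"B{i}": "B" for i in (1, 2, 3)})
    return GroupDesign(assignment, ["A", "B"])


@pytest.fixture
def random_matrix():
    """Seeded 30x6 log2-scale matrix with ~20% missing, >= 2 obs per peptide."""
    rng = np.random.default_rng(42)
    values = rng.normal(20.0, 2.0, size=(30, 6))
    mask = rng.random((30, 6)) > 0.2
    # keep every row and column identifiable
    mask[:, 0] = True
    mask[:, 1] = True
    return IntensityMatrix(
        values, mask,
        [f"pep{i}" for i in range(30)],
        ["A1", "A2", "A3", "B1", "B2", "B3"],
    )


def make_matrix(values, mask=None, run_ids=None):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.isfinite(values)
    m, n = values.shape
    if run_ids is None:
        run_ids = [f"run{j}" for j in range(n)]
    return IntensityMatrix(values, mask, [f"pep{i}" for i in range(m)], run_ids)


EVIDENCE_HEADER = "Modified sequence\tRaw file\tIntensity\tPotential contaminant\tReverse"


def write_evidence(path, rows):
    """Write a minimal MaxQuant-style evidence table."""
    with open(path, "w") as fh:
        fh.write(EVIDENCE_HEADER + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
    return path
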