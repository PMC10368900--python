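"""Readers, preprocessing and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from baryimpute import (
    InputError,
    IntensityMatrix,
    filter_min_observed,
    log2_transform,
    quantile_normalize,
    quantile_normalize_observed,
    read_maxquant_evidence,
    read_wide_matrix,
    write_wide_matrix,
)

from conftest import make_matrix, write_evidence


class TestReadWideMatrix:
    def test_blank_cell_is_masked(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tr1\tr2\npepA\t100\t\npepB\t200\t300\npepC\t400\t500\n")
        x = read_wide_matrix(str(p))
        assert (~x.mask).sum() == 1
        assert not x.mask[0, 1]
        assert x.values[1, 0] == 200

    def test_zero_cells_are_missing_by_default(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tr1\tr2\npepA\t0\t0\npepB\t0\t0\n")
        x = read_wide_matrix(str(p))
        assert not x.mask.any()

    def test_zero_token_can_be_disabled(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tr1\tr2\npepA\t0\t5\npepB\t1\t2\n")
        x = read_wide_matrix(str(p), missing_tokens={"", "NA"})
        assert x.mask.all()
        assert x.values[0, 0] == 0.0

    def test_duplicate_ids_error_names_duplicates(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tr1\tr2\npepA\t1\t2\npepA\t3\t4\n")
        with pytest.raises(InputError, match="pepA"):
            read_wide_matrix(str(p))

    def test_non_numeric_cell_error_reports_location(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("id\tr1\tr2\npepA\t1\tbogus\n" "pepB\t1\t2\n")
        with pytest.raises(InputError, match="pepA.*r2"):
            read_wide_matrix(str(p))

    def test_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        values = rng.uniform(1.0, 1e7, size=(10, 4))
        mask = rng.random((10, 4)) > 0.3
        x = make_matrix(np.where(mask, values, np.nan), mask)
        p = tmp_path / "rt.tsv"
        write_wide_matrix(x, str(p))
        y = read_wide_matrix(str(p))
        assert y.peptide_ids == x.peptide_ids
        assert y.run_ids == x.run_ids
        assert np.array_equal(y.mask, x.mask)
        assert np.array_equal(y.values[y.mask], x.values[x.mask])


class TestReadMaxquantEvidence:
    def test_highest_intensity_ion_retained(self, tmp_path):
        p = write_evidence(tmp_path / "ev.txt", [
            ("PEPTIDEK", "run1", "1e6", "", ""),
            ("PEPTIDEK", "run1", "3e6", "", ""),
            ("PEPTIDEK", "run2", "2e6", "", ""),
            ("OTHERPEP", "run1", "5e5", "", ""),
            ("OTHERPEP", "run2", "6e5", "", ""),
        ])
        x = read_maxquant_evidence(str(p))
        i = x.peptide_ids.index("PEPTIDEK")
        j = x.run_ids.index("run1")
        assert x.values[i, j] == 3e6

    def test_reverse_rows_excluded_even_if_only_evidence(self, tmp_path):
        p = write_evidence(tmp_path / "ev.txt", [
            ("DECOYPEP", "run1", "1e6", "", "+"),
            ("REALPEPA", "run1", "2e6", "", ""),
            ("REALPEPA", "run2", "1e6", "", ""),
        ])
        x = read_maxquant_evidence(str(p))
        assert "DECOYPEP" not in x.peptide_ids

    def test_contaminant_fixture_hand_count(self, tmp_path):
        # 5 peptides x 3 runs; PEP5 appears only in contaminant rows -> 4 rows
        rows = []
        for pep in ("PEP1", "PEP2", "PEP3", "PEP4"):
            for run in ("r1", "r2", "r3"):
                rows.append((pep, run, "1e6", "", ""))
        rows.append(("PEP5", "r1", "9e6", "+", ""))
        rows.append(("PEP5", "r2", "9e6", "+", ""))
        x = read_maxquant_evidence(str(write_evidence(tmp_path / "ev.txt", rows)))
        assert sorted(x.peptide_ids) == ["PEP1", "PEP2", "PEP3", "PEP4"]
        assert x.mask.all()

    def test_unquantified_cells_are_masked(self, tmp_path):
        p = write_evidence(tmp_path / "ev.txt", [
            ("PEPA", "r1", "1e6", "", ""),
            ("PEPA", "r2", "2e6", "", ""),
            ("PEPB", "r1", "3e6", "", ""),
        ])
        x = read_maxquant_evidence(str(p))
        i = x.peptide_ids.index("PEPB")
        j = x.run_ids.index("r2")
        assert not x.mask[i, j]

    def test_missing_required_column_listed(self, tmp_path):
        p = tmp_path / "ev.txt"
        p.write_text("Sequence\tRaw file\nPEPA\trun1\n")
        with pytest.raises(InputError, match="intensity"):
            read_maxquant_evidence(str(p))

    def test_plain_sequence_dialect_accepted(self, tmp_path):
        p = tmp_path / "ev.txt"
        p.write_text(
            "Sequence\tRaw file\tIntensity\n"
            "PEPA\tr1\t100\nPEPA\tr2\t200\nPEPB\tr1\t300\nPEPB\tr2\t400\n"
        )
        x = read_maxquant_evidence(str(p))
        assert x.shape == (2, 2)


class TestLog2Transform:
    def test_known_values(self):
        x = make_matrix([[8.0, 1.0], [4.0, 2.0]])
        y = log2_transform(x)
        assert np.allclose(y.values, [[3.0, 0.0], [2.0, 1.0]])
        assert np.array_equal(y.mask, x.mask)

    def test_nonpositive_observed_raises(self):
        x = make_matrix([[8.0, -1.0], [4.0, 2.0]])
        with pytest.raises(ValueError, match="positive"):
            log2_transform(x)

    def test_double_application_warns_on_small_scale(self):
        x = make_matrix([[8.0, 16.0], [4.0, 32.0]])
        y = log2_transform(x)
        with pytest.warns(UserWarning, match="log2 scale"):
            log2_transform(y)


class TestFilterMinObserved:
    def test_sparse_peptide_removed(self):
        values = np.full((2, 12), 20.0)
        mask = np.ones((2, 12), bool)
        mask[0, 3:] = False  # 3 of 12 observed
        x = make_matrix(np.where(mask, values, np.nan), mask)
        y, removed = filter_min_observed(x, 4)
        assert removed == ["pep0"]
        assert y.peptide_ids == ["pep1"]

    def test_fully_observed_unchanged(self, random_matrix):
        full = make_matrix(np.full((5, 4), 20.0))
        y, removed = filter_min_observed(full, 4)
        assert removed == []
        assert np.array_equal(y.values, full.values)

    def test_survivor_count_matches_brute_force(self):
        rng = np.random.default_rng(11)
        mask = rng.random((100, 8)) > 0.3
        values = np.where(mask, rng.normal(20, 2, (100, 8)), np.nan)
        x = make_matrix(values, mask)
        expected = sum(1 for i in range(100) if mask[i].sum() >= 4)
        y, removed = filter_min_observed(x, 4)
        assert y.shape[0] == expected
        assert len(removed) == 100 - expected

    def test_idempotent(self, random_matrix):
        y, _ = filter_min_observed(random_matrix, 3)
        z, removed = filter_min_observed(y, 3)
        assert removed == []
        assert np.array_equal(z.mask, y.mask)

    def test_nothing_survives_raises(self):
        x = make_matrix([[20.0, np.nan], [np.nan, 21.0]])
        with pytest.raises(ValueError, match="no peptides survive"):
            filter_min_observed(x, 2)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        col = np.array([1.0, 5.0, 3.0])
        x = make_matrix(np.column_stack([col, col]))
        y = quantile_normalize(x)
        assert np.allclose(y.values, x.values)

    def test_rank_mean_arithmetic(self):
        x = make_matrix(np.column_stack([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        y = quantile_normalize(x)
        assert np.allclose(y.values[:, 0], [2.5, 3.5, 4.5])
        assert np.allclose(y.values[:, 1], [2.5, 3.5, 4.5])

    def test_sorted_columns_identical_after(self):
        rng = np.random.default_rng(3)
        x = make_matrix(rng.normal(20, 2, size=(50, 5)))
        y = quantile_normalize(x)
        ref = np.sort(y.values[:, 0])
        for j in range(1, 5):
            assert np.allclose(np.sort(y.values[:, j]), ref, atol=1e-12)

    def test_ties_get_mean_of_reference_span(self):
        # column 0 has a tie at its two lowest ranks
        x = make_matrix(np.column_stack([[1.0, 1.0, 5.0], [2.0, 4.0, 6.0]]))
        y = quantile_normalize(x)
        ref = np.sort(x.values, axis=0).mean(axis=1)  # [1.5, 2.5, 5.5]
        assert np.allclose(y.values[:2, 0], (ref[0] + ref[1]) / 2)
        assert y.values[2, 0] == pytest.approx(ref[2])

    def test_incomplete_matrix_rejected(self, random_matrix):
        with pytest.raises(ValueError, match="complete"):
            quantile_normalize(random_matrix)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_idempotent_rank_and_mean_preserving(self, seed):
        rng = np.random.default_rng(seed)
        x = make_matrix(rng.normal(20, 2, size=(12, 4)))
        y = quantile_normalize(x)
        # grand mean preserved
        assert y.values.mean() == pytest.approx(x.values.mean(), abs=1e-9)
        # within-column rank order preserved
        for j in range(4):
            assert np.array_equal(
                np.argsort(y.values[:, j], kind="stable"),
                np.argsort(x.values[:, j], kind="stable"),
            )
        # idempotent
        z = quantile_normalize(y)
        assert np.allclose(z.values, y.values, atol=1e-12)


class TestQuantileNormalizeObserved:
    def test_masked_entries_stay_masked(self, random_matrix):
        y = quantile_normalize_observed(random_matrix)
        assert np.array_equal(y.mask, random_matrix.mask)

    def test_brings_shifted_columns_together(self):
        rng = np.random.default_rng(5)
        base = rng.normal(20, 2, size=(200, 1))
        values = np.hstack([base, base + 3.0])
        mask = rng.random((200, 2)) > 0.2
        x = make_matrix(np.where(mask, values, np.nan), mask)
        y = quantile_normalize_observed(x)
        med0 = np.median(y.values[y.mask[:, 0], 0])
        med1 = np.median(y.values[y.mask[:, 1], 1])
        assert abs(med0 - med1) < 0.2


class TestIntensityMatrixInvariants:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            IntensityMatrix(np.zeros((2, 3)), np.ones((3, 2), bool),
                            ["a", "b"], ["r1", "r2", "r3"])

    def test_single_run_rejected(self):
        with pytest.raises(ValueError, match="2 runs"):
            IntensityMatrix(np.zeros((2, 1)), np.ones((2, 1), bool),
                            ["a", "b"], ["r1"])

    def test_nonfinite_observed_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="finite"):
            IntensityMatrix(vals, np.ones((2, 2), bool), ["a", "b"], ["r1", "r2"])
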