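"""Matrix construction, cell bookkeeping, overlap/coverage statistics,
and the chemical space envelope."""

import pytest

from sarmatrix import (
    build_matrices,
    canonical_structure,
    enumerate_virtuals,
    matrix_coverage,
    matrix_overlap,
    matrix_stats,
    reassemble,
    row_overlap,
    space_envelope,
)
from sarmatrix.matrices import read_matrices_json, write_matrices_json
from sarmatrix.synthetic import LibraryConfig, generate_library

from conftest import make_matrix, matrix_with_rows, two_site_set, variant_cores


@pytest.fixture()
def three_row_set(small_pipeline):
    """Three analogous cores (F/Cl/Br on the two-site pyridine) x
    substituents; the methyl column is fully populated, the
    2-hydroxyethyl column occurs in one series only."""
    cells = [("F", "C"), ("Cl", "C"), ("Br", "C"), ("F", "OCC")]
    pki = {c: 6.0 + 0.1 * i for i, c in enumerate(cells)}
    cset = two_site_set(cells, pki)
    matrices = small_pipeline(cset)
    return cset, matrix_with_rows(matrices, variant_cores(("F", "Cl", "Br")))


class TestBuildSarms:
    def test_three_series_grid_fully_tiled(self, small_pipeline):
        """Three analog series over three shared substituents tile a
        3-row matrix in which every core x substituent cell exists."""
        cells = [(v, s) for v in ("F", "Cl", "Br") for s in ("C", "CC", "OC")]
        pki = {c: 6.0 for c in cells}
        cset = two_site_set(cells, pki)
        sarm = matrix_with_rows(small_pipeline(cset),
                                variant_cores(("F", "Cl", "Br")))
        assert sarm.n_columns >= 3 and sarm.n_real == 9
        assert len(sarm.cells) == sarm.n_rows * sarm.n_columns

    def test_min_real_drops_sparse_matrix(self, small_pipeline):
        cells = [("F", "C"), ("Cl", "CC")]
        cset = two_site_set(cells, {c: 6.0 for c in cells})
        assert small_pipeline(cset, min_real=3) == []
        kept = small_pipeline(cset, min_real=2)
        sarm = matrix_with_rows(kept, variant_cores(("F", "Cl")))
        assert sarm.n_real == 2
        assert sarm.n_rows * sarm.n_columns - sarm.n_real == 2

    def test_unknown_target_lists_available(self, small_pipeline):
        cells = [("F", "C"), ("Cl", "C"), ("Br", "C")]
        cset = two_site_set(cells, {c: 6.0 for c in cells})
        with pytest.raises(ValueError, match="T1"):
            small_pipeline(cset, target="T9")

    def test_unannotated_compound_stays_real(self, small_pipeline):
        cells = [("F", "C"), ("Cl", "C"), ("Br", "C")]
        cset = two_site_set(cells, None)  # structures only
        from sarmatrix import attach_activities
        attach_activities(cset, [
            {"compound_id": r.compound_id, "target_id": "T1", "pKi": 6.0}
            for r in list(cset)[:2]])
        sarm = matrix_with_rows(small_pipeline(cset),
                                variant_cores(("F", "Cl", "Br")))
        unannotated = [c for _, _, c in sarm.real_cells() if c.pki is None]
        assert len(unannotated) == 1 and unannotated[0].is_real

    def test_real_cells_reassemble_from_coordinates(self, three_row_set):
        _, sarm = three_row_set
        for ri, ci, cell in sarm.real_cells():
            assert reassemble(sarm.rows[ri], list(sarm.columns[ci])) == \
                cell.structure


class TestVirtuals:
    def test_count_complements_real_cells(self, three_row_set):
        _, sarm = three_row_set
        virtuals = enumerate_virtuals(sarm)
        assert len(virtuals) == sarm.n_rows * sarm.n_columns - sarm.n_real

    def test_virtual_structures_are_canonical_assemblies(self, three_row_set):
        _, sarm = three_row_set
        for ri, ci, cell in enumerate_virtuals(sarm):
            assert cell.structure == canonical_structure(cell.structure)
            assert cell.structure == reassemble(sarm.rows[ri],
                                                list(sarm.columns[ci]))

    def test_known_elsewhere_flagging(self, small_pipeline):
        """A virtual cell whose structure exists as a real compound in
        the data set is flagged.

        The situation needs a size flip: the octyl substituent outweighs
        the methyl-decorated core, so the data-set compound indexes under
        the chain key instead of the core and its cell in the core-rowed
        matrix stays virtual."""
        cells = [("CC", "C"), ("C", "C"), ("CC", "CCCCCCCC"),
                 ("C", "CCCCCCCC")]
        pki = {c: 6.0 for c in cells}
        cset = two_site_set(cells, pki)
        matrices = small_pipeline(cset)
        sarm = matrix_with_rows(matrices, variant_cores(("CC", "C")))
        enumerate_virtuals(sarm, cset)
        flagged = [c for _, _, c in sarm.virtual_cells() if c.known_elsewhere]
        assert [c.structure for c in flagged] == \
            [canonical_structure("Cc1ccc(CCCCCCCC)cn1")]


class TestOverlapAndCoverage:
    def test_full_column_scores_one(self):
        sarm = make_matrix([[6, 6], [6, None], [6, None]])
        assert row_overlap(sarm, 0) == 1.0

    def test_singleton_column_scores_zero(self):
        sarm = make_matrix([[6, 6], [6, None], [6, None]])
        assert row_overlap(sarm, 1) == 0.0

    def test_two_of_three_rows_scores_half(self):
        sarm = make_matrix([[6, 6], [6, 6], [6, None]])
        assert row_overlap(sarm, 1) == 0.5

    def test_single_row_matrix_is_undefined(self):
        sarm = make_matrix([[6, 6]])
        with pytest.raises(ValueError):
            row_overlap(sarm, 0)

    def test_matrix_overlap_is_mean_of_columns(self):
        sarm = make_matrix([[6, 6, 6], [6, 6, None], [6, None, None]])
        assert matrix_overlap(sarm) == pytest.approx((1.0 + 0.5 + 0.0) / 3)

    def test_coverage_formula(self):
        sarm = make_matrix([[6, 6, None, 6], [6, None, 6, None],
                            [None, 6, None, None]])
        assert matrix_coverage(sarm) == pytest.approx(6 / 12)

    def test_full_matrix_coverage_one(self):
        assert matrix_coverage(make_matrix([[6, 6], [6, 6]])) == 1.0

    def test_bounds_on_generated_libraries(self):
        """RO in [0,1] and C in (0,1] over matrices from random synthetic
        libraries."""
        for seed in (1, 2, 3):
            cset, _ = generate_library(LibraryConfig(
                n_scaffolds=2, n_core_variants=3, n_substituents=4,
                holdout_fraction=0.2, seed=seed))
            for sarm in build_matrices(cset, "T1"):
                stats = matrix_stats(sarm)
                assert all(0.0 <= ro <= 1.0 for ro in stats.row_overlaps)
                assert 0.0 < stats.coverage <= 1.0
                assert stats.n_matrix == sarm.n_real


class TestEnvelope:
    def test_deduplicates_and_tracks_sources(self):
        a = make_matrix([[6, None], [6, 6]], matrix_id="A")
        b = make_matrix([[6, None], [6, 6]], matrix_id="B")
        # same synthetic structure string in both matrices
        a.cells[(0, 1)].structure = b.cells[(0, 1)].structure = "SHARED"
        (entry,) = space_envelope([a, b])
        assert entry.structure == "SHARED" and entry.sources == ["A", "B"]

    def test_empty_for_full_matrices(self):
        assert space_envelope([make_matrix([[6, 6], [6, 6]])]) == []

    def test_size_bounded_by_total_virtual_count(self, small_pipeline):
        cset, _ = generate_library(LibraryConfig(
            n_scaffolds=2, n_core_variants=3, n_substituents=4,
            holdout_fraction=0.25, seed=9))
        matrices = build_matrices(cset, "T1")
        total = sum(len(m.virtual_cells()) for m in matrices)
        assert 0 < len(space_envelope(matrices)) <= total


class TestSerialization:
    def test_json_round_trip_preserves_layout_and_cells(self, tmp_path,
                                                        three_row_set):
        _, sarm = three_row_set
        path = tmp_path / "matrices.json"
        write_matrices_json([sarm], path)
        (again,) = read_matrices_json(path)
        assert again.rows == sarm.rows and again.columns == sarm.columns
        for coords, cell in sarm.cells.items():
            other = again.cells[coords]
            assert (cell.status, cell.structure, cell.compound_id, cell.pki) == \
                (other.status, other.structure, other.compound_id, other.pki)

    def test_json_bytes_stable(self, tmp_path, three_row_set):
        _, sarm = three_row_set
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_matrices_json([sarm], p1)
        write_matrices_json([sarm], p2)
        assert p1.read_bytes() == p2.read_bytes()
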