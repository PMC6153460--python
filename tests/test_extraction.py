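"""Greedy dense-submatrix extraction and its oracles."""

from fractions import Fraction

import numpy as np
import pytest

from profmat import (
    Axis,
    ExtractionConfig,
    LineStats,
    TernaryMatrix,
    brute_force_max_complete_submatrix,
    extract_dense_submatrix,
    line_score,
    matrix_density,
    select_assays_per_target,
    subset,
)
from profmat.io import AssayRecord

from conftest import matrix_from_codes, random_matrix


def _stats(density, hit_rate=0.0, axis=Axis.COMPOUND):
    return LineStats(
        line_id="x", axis=axis, n_tested=0, n_active=0,
        density=density, hit_rate=hit_rate,
    )


class TestLineScore:
    @pytest.mark.parametrize(
        "density, hit_rate, cfg, expected",
        [
            (0.5, 0.0, ExtractionConfig(activity_weight=0.0), 0.5),
            (0.5, 0.2, ExtractionConfig(activity_weight=1.0), 0.7),
            (0.5, 0.0, ExtractionConfig(compound_weight=2.0), 1.0),
        ],
    )
    def test_compound_scores(self, density, hit_rate, cfg, expected):
        assert line_score(_stats(density, hit_rate), cfg) == pytest.approx(expected)

    def test_axis_weight_selects_by_axis(self):
        cfg = ExtractionConfig(assay_weight=3.0, compound_weight=2.0)
        assert line_score(_stats(0.5), cfg) == pytest.approx(1.0)
        assert line_score(_stats(0.5, axis=Axis.ASSAY), cfg) == pytest.approx(1.5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"target_density": 0.0},
            {"target_density": 1.5},
            {"assay_weight": -1.0},
            {"activity_weight": -0.1},
        ],
    )
    def test_config_validation(self, kwargs):
        with pytest.raises(ValueError):
            ExtractionConfig(**kwargs)


class TestGreedyExtraction:
    def test_staircase_toy_trace(self, toy3x3):
        """Deletes r3 (density 1/3, compound-axis tie-break) then c3 (1/2)."""
        res = extract_dense_submatrix(toy3x3, ExtractionConfig(target_density=1.0))
        assert res.feasible
        assert [(s.axis, s.line_id) for s in res.trace] == [
            (Axis.COMPOUND, "r3"),
            (Axis.ASSAY, "c3"),
        ]
        assert res.trace[0].raw_density == pytest.approx(1 / 3)
        assert res.trace[1].raw_density == pytest.approx(1 / 2)
        assert res.matrix.compound_ids == ("r1", "r2")
        assert res.matrix.assay_ids == ("c1", "c2")
        assert res.achieved_density == 1.0
        assert res.selected_iteration == 2
        # greedy equals the exhaustive optimum here
        _, _, best_cells = brute_force_max_complete_submatrix(toy3x3)
        assert res.matrix.n_compounds * res.matrix.n_assays == best_cells == 4

    def test_already_complete_is_identity(self):
        m = matrix_from_codes([[1, 2], [2, 2]])
        res = extract_dense_submatrix(m)
        assert res.feasible and res.trace == () and res.matrix == m

    def test_single_untested_cell_infeasible(self):
        m = TernaryMatrix.from_cells(["r1"], ["c1"], {})
        res = extract_dense_submatrix(m)
        assert not res.feasible
        assert len(res.trace) == 1  # zero-tested pre-pass emptied the matrix
        assert res.matrix.is_empty

    def test_determinism_identical_traces(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 8, 8)
        r1 = extract_dense_submatrix(m)
        r2 = extract_dense_submatrix(m)
        assert r1.trace == r2.trace and r1.matrix == r2.matrix

    def test_result_is_faithful_submatrix(self):
        """No cell is created or mutated; result equals input restricted."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            m = random_matrix(rng)
            res = extract_dense_submatrix(m, ExtractionConfig(target_density=0.8))
            if res.matrix.is_empty:
                continue
            assert res.matrix == subset(
                m, res.matrix.compound_ids, res.matrix.assay_ids
            )

    def test_trace_matches_full_recomputation(self):
        """Incremental counts equal recomputation on the replayed subsets."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            m = random_matrix(rng)
            res = extract_dense_submatrix(m)
            kept_c = list(m.compound_ids)
            kept_a = list(m.assay_ids)
            for step in res.trace:
                if step.axis is Axis.COMPOUND:
                    kept_c.remove(step.line_id)
                else:
                    kept_a.remove(step.line_id)
                sub = subset(m, kept_c, kept_a)
                assert (sub.n_compounds, sub.n_assays) == (
                    step.n_rows_after,
                    step.n_cols_after,
                )
                if not sub.is_empty:
                    assert step.density_after == pytest.approx(
                        matrix_density(sub), abs=1e-15
                    )

    def test_monotone_density_with_default_weights(self):
        """Unweighted deletion never lowers overall density (exact check)."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            m = random_matrix(rng)
            res = extract_dense_submatrix(m)
            densities = [Fraction(m.n_cells, m.n_compounds * m.n_assays)]
            kept_c, kept_a = list(m.compound_ids), list(m.assay_ids)
            for step in res.trace:
                (kept_c if step.axis is Axis.COMPOUND else kept_a).remove(
                    step.line_id
                )
                sub = subset(m, kept_c, kept_a)
                if sub.is_empty:
                    break
                densities.append(
                    Fraction(sub.n_cells, sub.n_compounds * sub.n_assays)
                )
            assert all(b >= a for a, b in zip(densities, densities[1:]))


class TestBruteForceOracle:
    def test_fully_tested_matrix_is_its_own_optimum(self):
        m = matrix_from_codes([[2] * 3] * 3)
        rows, cols, cells = brute_force_max_complete_submatrix(m)
        assert cells == 9 and len(rows) == 3 and len(cols) == 3

    def test_no_tested_cells_gives_zero(self):
        m = matrix_from_codes([[0, 0], [0, 0]])
        assert brute_force_max_complete_submatrix(m) == ((), (), 0)

    def test_dimension_cap_enforced(self):
        m = matrix_from_codes([[2] * 3] * 13)
        with pytest.raises(ValueError, match="cap"):
            brute_force_max_complete_submatrix(m, max_dim=12)

    def test_greedy_never_beats_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            m = random_matrix(rng, max_dim=7)
            res = extract_dense_submatrix(m)
            greedy_cells = (
                res.matrix.n_compounds * res.matrix.n_assays if res.feasible else 0
            )
            _, _, best = brute_force_max_complete_submatrix(m)
            assert greedy_cells <= best


class TestAssaySelection:
    def _rec(self, aid, target, n, assay_type="confirmatory"):
        return AssayRecord(aid, target, "", assay_type, n)

    def test_largest_screen_wins(self):
        recs = [self._rec("A1", "T", 100), self._rec("A2", "T", 250)]
        assert [r.assay_id for r in select_assays_per_target(recs)] == ["A2"]

    def test_one_assay_per_target_is_identity(self):
        recs = [self._rec("A1", "T1", 10), self._rec("A2", "T2", 20)]
        assert select_assays_per_target(recs) == recs

    def test_tie_broken_by_smallest_assay_id(self):
        recs = [self._rec("A2", "T", 100), self._rec("A1", "T", 100)]
        assert [r.assay_id for r in select_assays_per_target(recs)] == ["A1"]

    def test_assay_types_selected_independently(self):
        recs = [
            self._rec("A1", "T", 100, "confirmatory"),
            self._rec("A2", "T", 50, "primary"),
        ]
        assert len(select_assays_per_target(recs)) == 2

    def test_duplicate_assay_id_rejected(self):
        recs = [self._rec("A1", "T", 1), self._rec("A1", "U", 2)]
        with pytest.raises(ValueError, match="duplicate assay_id"):
            select_assays_per_target(recs)

    def test_empty_input_empty_output(self):
        assert select_assays_per_target([]) == []
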