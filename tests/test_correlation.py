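"""Correlation matrices and thresholded graph construction."""

import numpy as np
import pytest

from corrgraph import CorrelationConfig, DataMatrix, build_correlation_graph, correlation_matrix
from oracles import scalar_correlation_matrix, scalar_pearson


def matrix_of(rows, prefix="r"):
    rows = np.asarray(rows, dtype=float)
    return DataMatrix(
        [f"{prefix}{i}" for i in range(rows.shape[0])],
        [f"c{j}" for j in range(rows.shape[1])],
        rows,
    )


class TestCorrelationMatrix:
    def test_perfect_linear(self):
        r = correlation_matrix(matrix_of([[1, 2, 3], [2, 4, 6]]))
        assert r[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_perfect_anti_linear(self):
        r = correlation_matrix(matrix_of([[1, 2, 3], [3, 2, 1]]))
        assert r[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_value(self):
        # scalar oracle gives 0.8 for these two rows
        assert scalar_pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
        r = correlation_matrix(matrix_of([[1, 2, 3, 4], [1, 3, 2, 4]]))
        assert r[0, 1] == pytest.approx(0.8, abs=1e-12)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_scalar_oracle(self, method):
        rng = np.random.default_rng(11)
        for _ in range(10):
            values = rng.normal(size=(8, 10))
            mine = correlation_matrix(matrix_of(values), method)
            ref = scalar_correlation_matrix(values, method)
            np.testing.assert_allclose(mine, ref, atol=1e-12)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(5)
        r = correlation_matrix(matrix_of(rng.normal(size=(15, 6))))
        np.testing.assert_allclose(r, r.T, atol=0)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert np.all(np.abs(r) <= 1.0)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(9)
        values = rng.normal(size=(6, 12))
        transformed = np.exp(3 * values)  # strictly monotone per row
        r1 = correlation_matrix(matrix_of(values), "spearman")
        r2 = correlation_matrix(matrix_of(transformed), "spearman")
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_pairwise_missing_short_overlap_gives_nan(self):
        values = np.array(
            [[1.0, 2.0, np.nan, np.nan, 5.0], [1.0, np.nan, 3.0, 4.0, np.nan]]
        )
        r = correlation_matrix(matrix_of(values))
        assert np.isnan(r[0, 1])  # only one shared observation

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match="2 columns"):
            correlation_matrix(matrix_of([[1.0], [2.0]]))


class TestBuildGraph:
    @pytest.fixture
    def planted_rows(self):
        rng = np.random.default_rng(21)
        a = rng.normal(size=20)
        return matrix_of([a, 2 * a, -a, rng.normal(size=20)], prefix="")

    def test_positive_only(self, planted_rows):
        g = build_correlation_graph(planted_rows, CorrelationConfig(r_min=0.9))
        assert set(g.edge_keys()) == {("0", "1")}
        assert g.weight("0", "1") == pytest.approx(1.0)

    def test_absolute_polarity_keeps_signed_weight(self, planted_rows):
        g = build_correlation_graph(
            planted_rows, CorrelationConfig(r_min=0.9, polarity="absolute")
        )
        assert set(g.edge_keys()) == {("0", "1"), ("0", "2"), ("1", "2")}
        assert g.weight("0", "2") == pytest.approx(-1.0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(33)
        m = matrix_of(rng.normal(size=(15, 8)))
        t1, t2 = sorted(rng.uniform(-0.5, 0.9, size=2))
        low = set(build_correlation_graph(m, CorrelationConfig(r_min=t1)).edge_keys())
        high = set(build_correlation_graph(m, CorrelationConfig(r_min=t2)).edge_keys())
        assert high <= low

    def test_blocked_equals_unblocked(self):
        rng = np.random.default_rng(13)
        m = matrix_of(rng.normal(size=(40, 10)))
        cfg = CorrelationConfig(r_min=0.3)
        g_small = build_correlation_graph(m, cfg, block_size=7)
        g_big = build_correlation_graph(m, cfg, block_size=4096)
        assert set(g_small.edge_keys()) == set(g_big.edge_keys())
        for u, v in g_small.edge_keys():
            assert g_small.weight(u, v) == pytest.approx(g_big.weight(u, v), abs=1e-12)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(17)
        values = rng.normal(size=(10, 9))
        cfg = CorrelationConfig(r_min=0.2)
        g1 = build_correlation_graph(matrix_of(values), cfg)
        g2 = build_correlation_graph(matrix_of(values[:, rng.permutation(9)]), cfg)
        assert set(g1.edge_keys()) == set(g2.edge_keys())

    def test_row_permutation_permutes_ids(self):
        rng = np.random.default_rng(19)
        values = rng.normal(size=(10, 9))
        cfg = CorrelationConfig(r_min=0.2)
        perm = rng.permutation(10)
        m1 = matrix_of(values)
        m2 = DataMatrix([m1.row_ids[i] for i in perm], m1.col_ids, values[perm])
        g1 = build_correlation_graph(m1, cfg)
        g2 = build_correlation_graph(m2, cfg)
        assert set(g1.edge_keys()) == set(g2.edge_keys())

    def test_annotations_copied_to_nodes(self):
        m = matrix_of([[1, 2, 3], [2, 4, 6]])
        m.row_annotations.set_column("Type", "categorical", {"r0": "x", "r1": "y"})
        g = build_correlation_graph(m, CorrelationConfig(r_min=0.5))
        assert g.node_attrs.get("Type", "r1") == "y"

    def test_impossible_threshold_warns(self):
        m = matrix_of([[1, 2, 3], [2, 4, 6]])
        with pytest.warns(UserWarning, match="no edge"):
            g = build_correlation_graph(m, CorrelationConfig(r_min=1.0))
        assert g.n_edges == 0 and g.n_nodes == 2

    def test_strict_vs_inclusive_comparison(self):
        strict = CorrelationConfig(r_min=0.85)
        inclusive = CorrelationConfig(r_min=0.85, inclusive=True)
        assert not strict.passes(0.85) and inclusive.passes(0.85)
        assert strict.passes(0.851) and not inclusive.passes(0.849)
        absolute = CorrelationConfig(r_min=0.85, polarity="absolute")
        assert absolute.passes(-0.9) and not strict.passes(-0.9)
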