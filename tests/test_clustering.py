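"""Louvain and MCL clustering, granularity mapping, cluster aggregation."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from corrgraph import (
    DataMatrix,
    GranularitySetting,
    Graph,
    aggregate_by_cluster,
    louvain,
    mcl,
)
from corrgraph.fixtures import PlantedPartitionSpec, planted_partition_graph
from oracles import best_modularity_partition, dense_mcl_clusters


def ari(labels, assignment, nodes):
    return adjusted_rand_score(
        [labels[n] for n in nodes], [assignment.label_of[n] for n in nodes]
    )


class TestLouvain:
    def test_two_triangles_matches_exhaustive_search(self, two_triangles_bridge):
        g = two_triangles_bridge
        a = louvain(g, GranularitySetting("louvain", 1.0, weighted=False))
        assert a.clusters() == {
            "Cluster 1": ["a", "b", "c"],
            "Cluster 2": ["d", "e", "f"],
        }
        best, best_q, n_partitions = best_modularity_partition(
            g.nodes, list(g.edges()), gamma=1.0
        )
        assert n_partitions == 203  # Bell(6)
        assert a.quality == pytest.approx(best_q, abs=1e-12)
        assert a.quality == pytest.approx(2 * (3 / 7 - (7 / 14) ** 2), abs=1e-12)
        assert sorted(map(sorted, best)) == [["a", "b", "c"], ["d", "e", "f"]]

    def test_edgeless_graph_singletons(self):
        g = Graph().add_nodes(["a", "b", "c"])
        a = louvain(g, GranularitySetting("louvain", 1.0))
        assert a.n_clusters == 3 and a.quality == 0.0

    def test_single_clique_one_cluster(self):
        g = Graph()
        names = list("abcde")
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(names[i], names[j])
        a = louvain(g, GranularitySetting("louvain", 1.0))
        assert a.n_clusters == 1

    def test_seed_reproducibility(self):
        g, _ = planted_partition_graph(PlantedPartitionSpec(seed=2))
        a1 = louvain(g, GranularitySetting("louvain", 1.0, seed=7))
        a2 = louvain(g, GranularitySetting("louvain", 1.0, seed=7))
        assert a1.label_of == a2.label_of and a1.quality == a2.quality

    def test_planted_partition_recovery_across_seeds(self):
        g, labels = planted_partition_graph(PlantedPartitionSpec(seed=1))
        good = sum(
            ari(labels, louvain(g, GranularitySetting("louvain", 1.0, seed=s)), g.nodes)
            >= 0.95
            for s in range(20)
        )
        assert good >= 19

    def test_quality_beats_singletons_and_trace_monotone(self):
        g, _ = planted_partition_graph(PlantedPartitionSpec(seed=5))
        a = louvain(g, GranularitySetting("louvain", 1.0))
        assert a.quality >= 0.0  # singleton partition has Q <= 0
        assert a.trace == sorted(a.trace)

    def test_higher_resolution_no_fewer_clusters(self):
        g, _ = planted_partition_graph(PlantedPartitionSpec(seed=3))
        counts = [
            louvain(g, GranularitySetting("louvain", gamma, seed=1)).n_clusters
            for gamma in (0.5, 1.0, 2.0)
        ]
        assert counts == sorted(counts)

    def test_hard_partition_and_naming(self, two_triangles_bridge):
        a = louvain(two_triangles_bridge, GranularitySetting("louvain", 1.0))
        assert sorted(a.label_of) == sorted(two_triangles_bridge.nodes)
        names = sorted(set(a.label_of.values()))
        assert names == [f"Cluster {i + 1}" for i in range(len(names))]


class TestMCL:
    def test_two_triangles_matches_dense_oracle(self, two_triangles_bridge):
        g = two_triangles_bridge
        a = mcl(g, GranularitySetting("mcl", 2.0))
        expected = dense_mcl_clusters(g.nodes, list(g.edges()), 2.0)
        assert expected == [["a", "b", "c"], ["d", "e", "f"]]
        assert a.clusters() == {
            "Cluster 1": ["a", "b", "c"],
            "Cluster 2": ["d", "e", "f"],
        }

    def test_disconnected_cliques_never_merge(self):
        g = Graph()
        for block in ("abc", "xyz"):
            for i in range(3):
                for j in range(i + 1, 3):
                    g.add_edge(block[i], block[j])
        for inflation in (1.3, 2.0, 5.0):
            assert mcl(g, GranularitySetting("mcl", inflation)).n_clusters == 2

    def test_inflation_monotone_cluster_count(self):
        g, _ = planted_partition_graph(PlantedPartitionSpec(seed=2))
        counts = [
            mcl(g, GranularitySetting("mcl", i)).n_clusters for i in (1.4, 2.0, 4.0, 6.0)
        ]
        assert counts == sorted(counts)

    def test_column_stochastic_after_inflation(self, two_triangles_bridge):
        # re-run the documented iteration and check the invariant directly
        import scipy.sparse as sp

        from corrgraph.clustering import _normalise_columns

        g = two_triangles_bridge
        nodes = sorted(g.nodes)
        idx = {n: i for i, n in enumerate(nodes)}
        n = len(nodes)
        dense = np.zeros((n, n))
        for u, v, w in g.edges():
            dense[idx[u], idx[v]] = dense[idx[v], idx[u]] = w
        for i in range(n):
            dense[i, i] = dense[i].max()
        m = _normalise_columns(sp.csc_array(dense))
        for _ in range(15):
            m = m @ m
            m.data **= 2.0
            m.data[m.data < 1e-5] = 0.0
            m.eliminate_zeros()
            m = _normalise_columns(m)
            np.testing.assert_allclose(
                np.asarray(m.sum(axis=0)).ravel(), 1.0, atol=1e-9
            )

    def test_hard_partition(self, two_triangles_bridge):
        a = mcl(two_triangles_bridge, GranularitySetting("mcl", 1.7))
        assert sorted(a.label_of) == sorted(two_triangles_bridge.nodes)

    def test_granularity_validation(self):
        with pytest.raises(ValueError, match="inflation"):
            GranularitySetting("mcl", 1.0)
        with pytest.raises(ValueError, match="resolution"):
            GranularitySetting("louvain", 0.0)


class TestAggregateByCluster:
    def make_assignment(self, mapping):
        from corrgraph import ClusterAssignment

        return ClusterAssignment(dict(mapping))

    def test_row_means(self):
        m = DataMatrix(
            ["r1", "r2", "r3", "r4"],
            ["c1", "c2"],
            np.array([[1.0, 2.0], [3.0, 4.0], [10.0, 20.0], [30.0, 40.0]]),
        )
        a = self.make_assignment(
            {"r1": "Cluster 1", "r2": "Cluster 1", "r3": "Cluster 2", "r4": "Cluster 2"}
        )
        agg = aggregate_by_cluster(m, a)
        assert agg.row_ids == ["Cluster 1", "Cluster 2"]
        np.testing.assert_allclose(agg.values, [[2.0, 3.0], [20.0, 30.0]])

    def test_singletons_identity_up_to_reordering(self):
        m = DataMatrix(["b", "a"], ["c1"], np.array([[2.0], [1.0]]))
        a = self.make_assignment({"a": "Cluster 1", "b": "Cluster 2"})
        agg = aggregate_by_cluster(m, a)
        assert agg.row_ids == ["Cluster 1", "Cluster 2"]
        np.testing.assert_allclose(agg.values, [[1.0], [2.0]])

    def test_column_aggregation(self):
        m = DataMatrix(
            ["g1"], ["c1", "c2", "c3"], np.array([[1.0, 3.0, 10.0]])
        )
        a = self.make_assignment(
            {"c1": "Cluster 1", "c2": "Cluster 1", "c3": "Cluster 2"}
        )
        agg = aggregate_by_cluster(m, a, axis="columns")
        assert agg.col_ids == ["Cluster 1", "Cluster 2"]
        np.testing.assert_allclose(agg.values, [[2.0, 10.0]])

    def test_missing_ids_error(self):
        m = DataMatrix(["r1", "r2"], ["c1"], np.zeros((2, 1)))
        a = self.make_assignment({"r1": "Cluster 1"})
        with pytest.raises(ValueError, match="r2"):
            aggregate_by_cluster(m, a)
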