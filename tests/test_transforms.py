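"""Transform stack: k-NN pruning, filters, component removal, contraction."""

import numpy as np
import pytest

from corrgraph import (
    Graph,
    TransformSpec,
    apply_stack,
    contract_edges,
    filter_edges,
    filter_nodes,
    knn_prune,
    remove_components,
)
from conftest import random_weighted_graph


class TestKnnPrune:
    def test_triangle_union_rule(self):
        g = Graph().add_edge("a", "b", 3).add_edge("b", "c", 2).add_edge("a", "c", 1)
        pruned = knn_prune(g, 1)
        # ab is top-1 of both a and b; bc is top-1 of c
        assert set(pruned.edge_keys()) == {("a", "b"), ("b", "c")}

    def test_identity_at_large_k(self):
        rng = np.random.default_rng(2)
        g = random_weighted_graph(rng)
        pruned = knn_prune(g, g.n_nodes)
        assert set(pruned.edge_keys()) == set(g.edge_keys())

    def test_star_keeps_all_leaf_edges(self):
        g = Graph()
        for i, leaf in enumerate("bcde"):
            g.add_edge("a", leaf, 0.1 * (i + 1))
        pruned = knn_prune(g, 1)
        # each leaf's only edge is its top-1, so the union rule keeps all
        assert pruned.n_edges == 4

    def test_union_rule_contract(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            g = random_weighted_graph(rng)
            k = int(rng.integers(1, 4))
            pruned = knn_prune(g, k)
            tops = {
                n: sorted(g.adjacency(n).items(), key=lambda it: -it[1])[:k]
                for n in g.nodes
            }
            # continuous weights: no ties, so top-k is unambiguous
            for u, v, w in pruned.edges():
                assert v in dict(tops[u]) or u in dict(tops[v])
            # every non-isolated node keeps its strongest edge
            for n in g.nodes:
                if g.adjacency(n):
                    best = max(g.adjacency(n).values())
                    assert best in pruned.adjacency(n).values()
            assert pruned.n_edges <= k * g.n_nodes

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        g = random_weighted_graph(rng)
        once = knn_prune(g, 2)
        twice = knn_prune(once, 2)
        assert set(once.edge_keys()) == set(twice.edge_keys())

    def test_mutual_rule_subset_of_union(self):
        rng = np.random.default_rng(12)
        g = random_weighted_graph(rng)
        assert set(knn_prune(g, 2, mutual=True).edge_keys()) <= set(
            knn_prune(g, 2).edge_keys()
        )

    def test_input_unmodified(self):
        g = Graph().add_edge("a", "b", 3).add_edge("b", "c", 2).add_edge("a", "c", 1)
        knn_prune(g, 1)
        assert g.n_edges == 3


class TestFilterEdges:
    def test_weight_threshold(self):
        g = Graph()
        g.add_edge("a", "b", 0.2).add_edge("b", "c", 0.5).add_edge("c", "d", 0.9)
        kept = filter_edges(g, lambda w: w >= 0.5)
        assert kept.n_edges == 2 and kept.n_nodes == 4

    def test_tautology_is_identity(self):
        rng = np.random.default_rng(1)
        g = random_weighted_graph(rng)
        assert set(filter_edges(g, lambda w: w >= 0).edge_keys()) == set(g.edge_keys())

    def test_frequency_attribute_rule(self):
        # drop low-support edges (observed fewer than 3 times)
        g = Graph()
        counts = {}
        for i, n in enumerate([1, 2, 3, 5]):
            u, v = f"x{i}", f"y{i}"
            g.add_edge(u, v)
            counts[(min(u, v), max(u, v))] = float(n)
        g.edge_attrs.set_column("n", "numeric", counts)
        kept = filter_edges(g, lambda n: n >= 3, attribute="n")
        assert kept.n_edges == 2

    def test_missing_attribute_named_in_error(self):
        g = Graph().add_edge("a", "b")
        with pytest.raises(KeyError, match="nope"):
            filter_edges(g, lambda v: True, attribute="nope")


class TestFilterNodes:
    def test_degree_rule_single_pass(self, path5):
        # a path a-b-c-d-e: ends have degree 1 and are removed; the rule is
        # applied against pre-removal degrees, so b-c-d all survive
        kept = filter_nodes(path5, lambda d: d >= 2, "Degree")
        assert set(kept.nodes) == {"b", "c", "d"}
        assert set(kept.edge_keys()) == {("b", "c"), ("c", "d")}

    def test_compound_predicate(self):
        g = Graph().add_edge("a", "b", 0.9).add_edge("b", "c", 0.3)
        g.degree()
        from corrgraph import annotate_max_edge_weight

        g = annotate_max_edge_weight(g)
        kept = filter_nodes(
            g,
            lambda r, d: not (r < 0.85 and d < 2),
            ["Max Edge Weight", "Degree"],
        )
        assert set(kept.nodes) == {"a", "b"}

    def test_remove_all(self, path5):
        assert filter_nodes(path5, lambda d: False, "Degree").n_nodes == 0

    def test_tautology_is_identity(self, path5):
        assert set(filter_nodes(path5, lambda d: True, "Degree").nodes) == set(path5.nodes)


class TestRemoveComponents:
    def test_size_threshold(self):
        g = Graph()
        for u, v in [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"),
                     ("x", "y"), ("y", "z")]:
            g.add_edge(u, v)
        g.add_node("solo")
        kept = remove_components(g, 2)
        assert kept.components().sizes == [5, 3]

    def test_min_one_is_identity(self, two_triangles_bridge):
        kept = remove_components(two_triangles_bridge, 1)
        assert set(kept.nodes) == set(two_triangles_bridge.nodes)

    def test_above_largest_empties(self, two_triangles_bridge):
        assert remove_components(two_triangles_bridge, 100).n_nodes == 0

    def test_surviving_internal_structure_untouched(self):
        rng = np.random.default_rng(6)
        g = random_weighted_graph(rng, n_max=10, p=0.3)
        kept = remove_components(g, 2)
        for u, v, w in kept.edges():
            assert g.weight(u, v) == w


class TestContractEdges:
    def test_path_full_contraction(self):
        g = Graph().add_edge("a", "b", 1).add_edge("b", "c", 1)
        out = contract_edges(g, lambda w: True)
        assert out.nodes == ["a"]
        assert out.node_attrs.get("Members", "a") == "a;b;c"
        assert out.node_attrs.get("Member Count", "a") == 3

    def test_no_match_is_identity(self):
        g = Graph().add_edge("a", "b", 0.4)
        out = contract_edges(g, lambda w: w > 1)
        assert set(out.nodes) == {"a", "b"} and out.n_edges == 1

    def test_square_parallel_collapse(self):
        g = Graph()
        g.add_edge("a", "b", 5).add_edge("b", "c", 1).add_edge("c", "d", 5).add_edge("d", "a", 2)
        out = contract_edges(g, lambda w: w >= 5)  # contract ab and cd
        assert set(out.nodes) == {"a", "c"}
        assert out.n_edges == 1
        # parallels b-c (1) and d-a (2) collapse to max weight
        assert out.weight("a", "c") == 2.0

    def test_members_count_conserved(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            g = random_weighted_graph(rng)
            out = contract_edges(g, lambda w: w > 0.5)
            total = sum(
                int(out.node_attrs.get("Member Count", n)) for n in out.nodes
            )
            assert total == g.n_nodes


class TestApplyStack:
    def test_composition_matches_manual(self):
        rng = np.random.default_rng(31)
        g = random_weighted_graph(rng, n_max=12, p=0.3)
        stack = [
            TransformSpec("filter_edges", {"op": ">=", "value": 0.3}),
            TransformSpec("knn", {"k": 2}),
            TransformSpec("remove_components", {"min_nodes": 2}),
        ]
        stacked = apply_stack(g, stack)
        manual = remove_components(
            knn_prune(filter_edges(g, lambda w: w >= 0.3), 2), 2
        )
        assert set(stacked.nodes) == set(manual.nodes)
        assert set(stacked.edge_keys()) == set(manual.edge_keys())

    def test_empty_stack_identity(self, path5):
        assert apply_stack(path5, []) is path5

    def test_unknown_transform_rejected(self):
        with pytest.raises(ValueError, match="unknown transform"):
            TransformSpec("explode", {})

    def test_unknown_params_rejected(self):
        with pytest.raises(ValueError, match="unknown parameters"):
            TransformSpec("knn", {"k": 3, "frobnicate": True})

    def test_missing_value_rejected(self):
        with pytest.raises(ValueError, match="value"):
            TransformSpec("filter_edges", {"op": ">="})
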