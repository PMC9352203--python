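"""Synthetic data generators with planted ground truth.

Every generator is a first-class, seeded, bit-reproducible source of test
surfaces: correlation matrices with planted co-expression modules, graphs
with planted community structure, trees, and a dosage-style integer matrix
mimicking genotype data (values 0/1/2 with block-correlated columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import CATEGORICAL, NUMERIC, Graph
from .matrix import DataMatrix


@dataclass(frozen=True)
class PlantedModuleSpec:
    """Latent-profile model for matrices with planted correlated row modules.

    Each module has one latent profile (standard normal over the columns);
    each member row is the latent plus independent Gaussian noise scaled so
    the expected within-module Pearson correlation is ``rho``.  Rows from
    different modules are independent.
    """

    n_modules: int = 5
    rows_per_module: int = 20
    n_cols: int = 30
    rho: float = 0.95
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")
        if min(self.n_modules, self.rows_per_module, self.n_cols) < 1:
            raise ValueError("dimensions must be positive")

    @property
    def noise_sd(self) -> float:
        # corr(latent + e1, latent + e2) = 1 / (1 + sd^2) for unit-variance latent
        return float(np.sqrt(1.0 / self.rho - 1.0))


def planted_module_matrix(spec: PlantedModuleSpec) -> tuple[DataMatrix, dict]:
    """Generate (matrix, true labels); labels map row id -> module name."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    row_ids = []
    labels = {}
    for m in range(spec.n_modules):
        latent = rng.standard_normal(spec.n_cols)
        for r in range(spec.rows_per_module):
            row_ids.append(f"M{m + 1}R{r + 1}")
            labels[row_ids[-1]] = f"module{m + 1}"
            rows.append(latent + spec.noise_sd * rng.standard_normal(spec.n_cols))
    matrix = DataMatrix(
        row_ids,
        [f"obs{j + 1}" for j in range(spec.n_cols)],
        np.array(rows),
    )
    matrix.row_annotations.set_column("Module", CATEGORICAL, labels)
    return matrix, labels


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Planted-partition (stochastic block model) graph specification."""

    block_sizes: tuple = (20, 20, 20, 20)
    p_in: float = 0.3
    p_out: float = 0.02
    weight_in: tuple = (0.8, 1.0)  # weight range for within-block edges
    weight_out: tuple = (0.1, 0.3)  # weight range for cross-block edges
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")


def planted_partition_graph(spec: PlantedPartitionSpec) -> tuple[Graph, dict]:
    """Generate (graph, true labels); labels map node id -> block name."""
    rng = np.random.default_rng(spec.seed)
    graph = Graph()
    labels = {}
    node_block = []
    for b, size in enumerate(spec.block_sizes):
        for i in range(size):
            node = f"B{b + 1}N{i + 1}"
            graph.add_node(node)
            labels[node] = f"block{b + 1}"
            node_block.append((node, b))
    for i in range(len(node_block)):
        u, bu = node_block[i]
        for j in range(i + 1, len(node_block)):
            v, bv = node_block[j]
            same = bu == bv
            p = spec.p_in if same else spec.p_out
            if rng.random() < p:
                lo, hi = spec.weight_in if same else spec.weight_out
                graph.add_edge(u, v, float(rng.uniform(lo, hi)))
    graph.node_attrs.set_column("Block", CATEGORICAL, labels)
    return graph, labels


def toy_tree(depth: int, branching: int) -> Graph:
    """Rooted tree as an undirected graph with a numeric "Level" attribute.

    A stand-in for taxonomy-style tree graphs: depth 0 is just the root;
    each internal node has ``branching`` children.
    """
    if depth < 0 or branching < 1:
        raise ValueError("need depth >= 0 and branching >= 1")
    graph = Graph()
    levels = {"n0": 0.0}
    graph.add_node("n0")
    frontier = ["n0"]
    counter = 1
    for level in range(1, depth + 1):
        next_frontier = []
        for parent in frontier:
            for _ in range(branching):
                child = f"n{counter}"
                counter += 1
                graph.add_edge(parent, child)
                levels[child] = float(level)
                next_frontier.append(child)
        frontier = next_frontier
    graph.node_attrs.set_column("Level", NUMERIC, levels)
    return graph


def dosage_matrix(
    n_individuals: int = 60,
    n_variants: int = 120,
    n_blocks: int = 4,
    seed: int = 1,
) -> tuple[DataMatrix, dict]:
    """Genotype-dosage-style matrix: integers 0/1/2, block-correlated columns.

    Individuals (rows) belong to latent populations; variants (columns) come
    in linkage-style blocks whose allele frequencies differ per population,
    so both row-wise (individual) and column-wise (variant, after transpose)
    correlation structure is planted.  Returns (matrix, population labels).
    """
    rng = np.random.default_rng(seed)
    pops = rng.integers(0, n_blocks, size=n_individuals)
    # per-population, per-block allele frequencies
    block_of_variant = rng.integers(0, n_blocks, size=n_variants)
    freq = rng.uniform(0.05, 0.95, size=(n_blocks, n_blocks))
    values = np.empty((n_individuals, n_variants))
    for i in range(n_individuals):
        p = freq[pops[i], block_of_variant]
        values[i] = rng.binomial(2, p)
    row_ids = [f"ind{i + 1}" for i in range(n_individuals)]
    labels = {r: f"pop{pops[i] + 1}" for i, r in enumerate(row_ids)}
    matrix = DataMatrix(
        row_ids, [f"snv{j + 1}" for j in range(n_variants)], values
    )
    matrix.row_annotations.set_column("Population", CATEGORICAL, labels)
    return matrix, labels


def random_attributed_graph(
    n_nodes: int = 50, edge_prob: float = 0.15, seed: int = 1
) -> Graph:
    """Random weighted graph with one categorical and one numeric attribute.

    Used for I/O round-trip and transform-contract testing.
    """
    rng = np.random.default_rng(seed)
    graph = Graph()
    names = [f"v{i:03d}" for i in range(n_nodes)]
    graph.add_nodes(names)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                graph.add_edge(names[i], names[j], float(rng.uniform(0.05, 1.0)))
    graph.node_attrs.set_column(
        "Group",
        CATEGORICAL,
        {n: f"g{int(rng.integers(0, 4))}" for n in names},
    )
    graph.node_attrs.set_column(
        "Score", NUMERIC, {n: float(np.round(rng.uniform(0, 10), 6)) for n in names}
    )
    graph.edge_attrs.set_column(
        "Confidence",
        NUMERIC,
        {(u, v): float(np.round(rng.uniform(0, 1), 6)) for u, v, _ in graph.edges()},
    )
    return graph
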