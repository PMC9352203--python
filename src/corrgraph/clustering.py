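"""Graph clustering: Louvain modularity optimisation and Markov clustering.

Both algorithms expose a single "granularity" knob controlling cluster
size/number:

* Louvain — granularity is the resolution parameter gamma in the modularity
  Q(gamma) = sum_c [ e_c/m - gamma * (d_c / 2m)^2 ], where e_c is the total
  intra-cluster edge weight, d_c the total weighted degree of cluster c and
  m the total edge weight.  Larger gamma -> more, smaller clusters.
* MCL — granularity is the inflation exponent.  Larger inflation -> more,
  smaller clusters.

Cluster labels are "Cluster 1".."Cluster N", ordered by descending size
(ties broken by the smallest member id), matching the convention of naming
the largest cluster first.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components as _sparse_components

from .graph import CATEGORICAL, Graph
from .matrix import DataMatrix

MCL = "mcl"
LOUVAIN = "louvain"


@dataclass(frozen=True)
class GranularitySetting:
    algorithm: str
    granularity: float
    weighted: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if self.algorithm not in (MCL, LOUVAIN):
            raise ValueError(f"unknown clustering algorithm {self.algorithm!r}")
        if self.algorithm == MCL and not self.granularity > 1:
            raise ValueError("MCL granularity (inflation) must be > 1")
        if self.algorithm == LOUVAIN and not self.granularity > 0:
            raise ValueError("Louvain granularity (resolution) must be > 0")


@dataclass
class ClusterAssignment:
    """Hard partition of the node set, clusters named by descending size."""

    label_of: dict
    quality: float | None = None  # modularity for Louvain; None for MCL
    trace: list | None = None  # per-level modularity (Louvain internal record)

    def clusters(self) -> dict:
        out: dict[str, list] = {}
        for node, label in self.label_of.items():
            out.setdefault(label, []).append(node)
        return out

    @property
    def n_clusters(self) -> int:
        return len(set(self.label_of.values()))

    def sizes(self) -> list[int]:
        from collections import Counter

        counts = Counter(self.label_of.values())
        return [counts[f"Cluster {i + 1}"] for i in range(len(counts))]


def _name_clusters(groups: list[list]) -> dict:
    """Assign "Cluster i" names by descending size, ties by smallest member."""
    ordered = sorted(
        (sorted(g) for g in groups), key=lambda g: (-len(g), g[0])
    )
    label_of = {}
    for i, members in enumerate(ordered):
        for node in members:
            label_of[node] = f"Cluster {i + 1}"
    return label_of


# ---------------------------------------------------------------------------
# Louvain


def _modularity_from_partition(adj, loops, community, gamma, m):
    """Q(gamma) for a partition of the internal multigraph representation."""
    e_c: dict[int, float] = {}
    d_c: dict[int, float] = {}
    n = len(adj)
    for i in range(n):
        ci = community[i]
        k_i = sum(adj[i].values()) + 2.0 * loops[i]
        d_c[ci] = d_c.get(ci, 0.0) + k_i
        e_c[ci] = e_c.get(ci, 0.0) + loops[i]
        for j, w in adj[i].items():
            if i < j and community[j] == ci:
                e_c[ci] = e_c.get(ci, 0.0) + w
    q = 0.0
    for c in d_c:
        q += e_c.get(c, 0.0) / m - gamma * (d_c[c] / (2.0 * m)) ** 2
    return q


def _local_move(adj, loops, gamma, m, rng, min_gain=1e-9):
    """One Louvain level: greedy node moves to convergence.

    Returns the community index per node.  Nodes are visited in an order
    shuffled by ``rng``; a node moves to the neighbouring community with the
    highest modularity gain, staying put on ties.
    """
    n = len(adj)
    k = [sum(adj[i].values()) + 2.0 * loops[i] for i in range(n)]
    community = list(range(n))
    sigma_tot = list(k)

    order = list(range(n))
    rng.shuffle(order)
    improved = True
    while improved:
        improved = False
        for i in order:
            ci = community[i]
            # weights from i to each neighbouring community (excluding loops)
            w_to: dict[int, float] = {}
            for j, w in adj[i].items():
                w_to[community[j]] = w_to.get(community[j], 0.0) + w
            # remove i from its community
            sigma_tot[ci] -= k[i]
            base = w_to.get(ci, 0.0) / m - gamma * k[i] * sigma_tot[ci] / (
                2.0 * m * m
            )
            best_c, best_gain = ci, base
            for c, w in w_to.items():
                if c == ci:
                    continue
                gain = w / m - gamma * k[i] * sigma_tot[c] / (2.0 * m * m)
                if gain > best_gain + min_gain:
                    best_c, best_gain = c, gain
            community[i] = best_c
            sigma_tot[best_c] += k[i]
            if best_c != ci:
                improved = True
    return community


def _aggregate(adj, loops, community):
    """Collapse communities into single nodes, accumulating weights."""
    comms = sorted(set(community))
    remap = {c: i for i, c in enumerate(comms)}
    n_new = len(comms)
    new_adj = [dict() for _ in range(n_new)]
    new_loops = [0.0] * n_new
    for i in range(len(adj)):
        ci = remap[community[i]]
        new_loops[ci] += loops[i]
        for j, w in adj[i].items():
            if i < j:
                cj = remap[community[j]]
                if ci == cj:
                    new_loops[ci] += w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                    new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    return new_adj, new_loops, remap


def louvain(graph: Graph, setting: GranularitySetting) -> ClusterAssignment:
    """Multi-level greedy modularity optimisation with resolution gamma.

    Local-move phases run to convergence, the graph is then aggregated by
    community, and the cycle repeats until no further modularity gain above
    1e-9.  The node visit order is shuffled from ``setting.seed``, making
    runs with a fixed seed bit-reproducible.  An edgeless graph yields
    singleton clusters with Q = 0.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes = graph.nodes
    if graph.n_edges == 0:
        return ClusterAssignment(_name_clusters([[n] for n in nodes]), quality=0.0)

    index = {n: i for i, n in enumerate(nodes)}
    adj = [dict() for _ in nodes]
    for u, v, w in graph.edges():
        wt = w if setting.weighted else 1.0
        adj[index[u]][index[v]] = wt
        adj[index[v]][index[u]] = wt
    loops = [0.0] * len(nodes)
    m = sum(sum(d.values()) for d in adj) / 2.0

    rng = random.Random(setting.seed)
    # membership[i] = current community (in the aggregated graph) of original node i
    membership = list(range(len(nodes)))
    trace = []
    q_prev = _modularity_from_partition(adj, loops, membership, setting.granularity, m)
    while True:
        community = _local_move(adj, loops, setting.granularity, m, rng)
        q = _modularity_from_partition(adj, loops, community, setting.granularity, m)
        if q <= q_prev + 1e-9 and trace:
            break
        trace.append(q)
        adj, loops, remap = _aggregate(adj, loops, community)
        membership = [remap[community[c]] for c in membership]
        if len(adj) == len(community):
            q_prev = q
            break
        q_prev = q

    groups: dict[int, list] = {}
    for node, c in zip(nodes, membership):
        groups.setdefault(c, []).append(node)
    return ClusterAssignment(
        _name_clusters(list(groups.values())), quality=q_prev, trace=trace
    )


# ---------------------------------------------------------------------------
# Markov clustering


def mcl(
    graph: Graph,
    setting: GranularitySetting,
    prune_threshold: float = 1e-5,
    conv_tol: float = 1e-8,
    max_iter: int = 100,
) -> ClusterAssignment:
    """Markov clustering on the (weighted) adjacency matrix.

    Self-loops with weight equal to the node's maximum incident weight are
    added to damp odd-cycle parity effects, columns are normalised to a
    stochastic flow matrix, and expansion (matrix squaring) alternates with
    inflation (entrywise power ``granularity`` + column renormalisation,
    pruning entries below ``prune_threshold``) until the matrix changes by
    less than ``conv_tol`` or ``max_iter`` iterations.  Clusters are the
    connected components of the limit matrix's nonzero structure.
    """
    if graph.n_nodes == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    rows, cols, data = [], [], []
    any_negative = False
    for u, v, w in graph.edges():
        wt = abs(w) if setting.weighted else 1.0
        any_negative = any_negative or w < 0
        rows += [index[u], index[v]]
        cols += [index[v], index[u]]
        data += [wt, wt]
    if any_negative:
        warnings.warn("negative edge weights: MCL uses their absolute values")
    loop = np.ones(n)
    for node in nodes:
        inc = graph.adjacency(node)
        if inc:
            loop[index[node]] = (
                max(abs(w) for w in inc.values()) if setting.weighted else 1.0
            )
    rows += list(range(n))
    cols += list(range(n))
    data += list(loop)
    m = sp.csc_array((data, (rows, cols)), shape=(n, n))

    m = _normalise_columns(m)
    for _ in range(max_iter):
        prev = m.copy()
        m = m @ m  # expansion
        m.data **= setting.granularity  # inflation
        m.data[m.data < prune_threshold] = 0.0
        m.eliminate_zeros()
        m = _normalise_columns(m)
        if abs(m - prev).max() < conv_tol:
            break
    else:
        warnings.warn(f"MCL did not converge within {max_iter} iterations")

    structure = m + m.T
    n_comp, labels = _sparse_components(structure, directed=False)
    groups: dict[int, list] = {}
    for node, lab in zip(nodes, labels):
        groups.setdefault(int(lab), []).append(node)
    return ClusterAssignment(_name_clusters(list(groups.values())), quality=None)


def _normalise_columns(m: sp.csc_array) -> sp.csc_array:
    sums = np.asarray(m.sum(axis=0)).ravel()
    sums[sums == 0] = 1.0
    scale = sp.dia_array((1.0 / sums[None, :], [0]), shape=m.shape)
    return (m @ scale).tocsc()


# ---------------------------------------------------------------------------
# cluster-level aggregation


def annotate_clusters(graph: Graph, assignment: ClusterAssignment, name: str) -> None:
    """Store cluster labels as a categorical node attribute."""
    graph.node_attrs.set_column(name, CATEGORICAL, assignment.label_of)


def aggregate_by_cluster(
    matrix: DataMatrix, assignment: ClusterAssignment, axis: str = "rows"
) -> DataMatrix:
    """Mean profile per cluster over the clustered axis.

    With ``axis="rows"`` the matrix rows are the clustered elements and the
    output has one row per cluster (ids = cluster names); ``axis="columns"``
    averages columns instead (e.g. per-cell columns into cell-cluster
    columns).  Ids present in the matrix but absent from the assignment (or
    vice versa) raise an error listing the missing ids.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    ids = matrix.row_ids if axis == "rows" else matrix.col_ids
    missing = [i for i in ids if i not in assignment.label_of]
    if missing:
        raise ValueError(f"ids without cluster assignment: {missing[:20]}")

    names = sorted(
        set(assignment.label_of[i] for i in ids),
        key=lambda s: int(s.rsplit(" ", 1)[1]),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if axis == "rows":
            blocks = [
                np.nanmean(
                    matrix.values[[k for k, r in enumerate(ids) if assignment.label_of[r] == c]],
                    axis=0,
                )
                for c in names
            ]
            return DataMatrix(names, list(matrix.col_ids), np.vstack(blocks))
        blocks = [
            np.nanmean(
                matrix.values[:, [k for k, c_id in enumerate(ids) if assignment.label_of[c_id] == c]],
                axis=1,
            )
            for c in names
        ]
        return DataMatrix(list(matrix.row_ids), names, np.column_stack(blocks))
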