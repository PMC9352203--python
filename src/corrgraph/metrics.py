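"""Node and edge analytics stored as attribute columns.

PageRank uses edge weights as transition proportions; betweenness and
eccentricity use unweighted hop distances, because correlation-graph
weights are similarities, not path costs.  Betweenness values are raw
(unnormalised) pair counts with endpoints excluded; encodings rescale for
display anyway.
"""

from __future__ import annotations

from collections import deque

import numpy as np

from .graph import NUMERIC, Graph, edge_key


def pagerank(
    graph: Graph,
    damping: float = 0.85,
    tol: float = 1e-10,
    max_iter: int = 200,
    store: bool = True,
) -> dict:
    """Damped random-walk stationary distribution via power iteration.

    Undirected edges act bidirectionally, with transition probability
    proportional to edge weight.  Teleportation is uniform over all nodes;
    dangling (isolated) nodes redistribute their mass uniformly.  Converges
    when the L1 change falls below ``tol``; the result sums to 1.
    """
    nodes = graph.nodes
    n = len(nodes)
    if n == 0:
        raise ValueError("PageRank is undefined on an empty graph")
    index = {node: i for i, node in enumerate(nodes)}

    out_weight = np.zeros(n)
    edges = []
    for u, v, w in graph.edges():
        if w < 0:
            raise ValueError("PageRank requires non-negative edge weights")
        i, j = index[u], index[v]
        edges.append((i, j, w))
        out_weight[i] += w
        out_weight[j] += w

    x = np.full(n, 1.0 / n)
    dangling = out_weight == 0
    for _ in range(max_iter):
        new = np.zeros(n)
        for i, j, w in edges:
            new[j] += x[i] * w / out_weight[i]
            new[i] += x[j] * w / out_weight[j]
        dangling_mass = x[dangling].sum()
        new = damping * (new + dangling_mass / n) + (1.0 - damping) / n
        if np.abs(new - x).sum() < tol:
            x = new
            break
        x = new
    else:
        residual = np.abs(new - x).sum()
        raise RuntimeError(
            f"PageRank did not converge in {max_iter} iterations "
            f"(residual {residual:.3e})"
        )
    values = {node: float(x[index[node]]) for node in nodes}
    if store:
        graph.node_attrs.set_column("PageRank", NUMERIC, values)
    return values


def betweenness(graph: Graph, store: bool = True) -> tuple[dict, dict]:
    """Brandes betweenness for nodes and edges on hop-count shortest paths.

    Returns raw counts of shortest-path pairs passing through each element:
    each unordered pair {s, t} contributes the fraction of s-t shortest
    paths using the element.  Endpoints are excluded from node scores.
    Computed independently within each component.
    """
    nodes = graph.nodes
    node_bc = {n: 0.0 for n in nodes}
    edge_bc = {ek: 0.0 for ek in ((u, v) for u, v, _ in graph.edges())}

    for s in nodes:
        # single-source shortest-path counting (BFS)
        stack = []
        pred: dict[str, list] = {n: [] for n in nodes}
        sigma = {n: 0.0 for n in nodes}
        dist = {n: -1 for n in nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            u = queue.popleft()
            stack.append(u)
            for v in graph.adjacency(u):
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    pred[v].append(u)
        # accumulation
        delta = {n: 0.0 for n in nodes}
        while stack:
            v = stack.pop()
            for u in pred[v]:
                contrib = sigma[u] / sigma[v] * (1.0 + delta[v])
                edge_bc[edge_key(u, v)] += contrib
                delta[u] += contrib
            if v != s:
                node_bc[v] += delta[v]

    # undirected: each pair was counted from both endpoints
    node_values = {n: v / 2.0 for n, v in node_bc.items()}
    edge_values = {ek: v / 2.0 for ek, v in edge_bc.items()}
    if store:
        graph.node_attrs.set_column("Betweenness", NUMERIC, node_values)
        graph.edge_attrs.set_column("Betweenness", NUMERIC, edge_values)
    return node_values, edge_values


def eccentricity(graph: Graph, store: bool = True) -> tuple[dict, dict]:
    """Maximum hop distance to any node in the same component.

    Isolated nodes get eccentricity 0.  The edge value is the maximum of
    its endpoints' eccentricities (a display convention; the quantity is
    defined on nodes).
    """
    node_values = {}
    for s in graph.nodes:
        dist = {s: 0}
        queue = deque([s])
        far = 0
        while queue:
            u = queue.popleft()
            for v in graph.adjacency(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    far = max(far, dist[v])
                    queue.append(v)
        node_values[s] = float(far)
    edge_values = {
        (u, v): max(node_values[u], node_values[v]) for u, v, _ in graph.edges()
    }
    if store:
        graph.node_attrs.set_column("Eccentricity", NUMERIC, node_values)
        graph.edge_attrs.set_column("Eccentricity", NUMERIC, edge_values)
    return node_values, edge_values
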