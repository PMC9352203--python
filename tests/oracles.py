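"""Independent reference implementations used only to check the package.

Each oracle is deliberately naive (scalar loops, brute-force enumeration,
dense linear algebra) and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def scalar_pearson(x, y) -> float:
    """Two-pass textbook Pearson correlation of two sequences."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    dx = math.sqrt(sum((a - mx) ** 2 for a in x))
    dy = math.sqrt(sum((b - my) ** 2 for b in y))
    return num / (dx * dy)


def scalar_ranks(x) -> list:
    """Average ranks with ties, computed by sorting scalar-style."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def scalar_spearman(x, y) -> float:
    return scalar_pearson(scalar_ranks(x), scalar_ranks(y))


def scalar_correlation_matrix(values, method="pearson"):
    f = scalar_pearson if method == "pearson" else scalar_spearman
    n = len(values)
    out = [[1.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            out[i][j] = out[j][i] = f(list(values[i]), list(values[j]))
    return np.array(out)


def brute_force_betweenness(nodes, adjacency):
    """All-pairs shortest-path enumeration betweenness (nodes and edges).

    ``adjacency``: dict node -> iterable of neighbours.  Enumerates every
    shortest path between every unordered pair by BFS + recursive path
    expansion, then counts the fraction passing through each element.
    """
    node_bc = {n: 0.0 for n in nodes}
    edge_bc = {}
    for u in adjacency:
        for v in adjacency[u]:
            edge_bc[(min(u, v), max(u, v))] = 0.0

    def all_shortest_paths(s, t):
        dist = {s: 0}
        parents = {s: []}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    parents[v] = [u]
                    queue.append(v)
                elif dist[v] == dist[u] + 1:
                    parents[v].append(u)
        if t not in dist:
            return []
        paths = []

        def expand(node, suffix):
            if node == s:
                paths.append([s] + suffix)
                return
            for p in parents[node]:
                expand(p, [node] + suffix)

        expand(t, [])
        return paths

    node_list = sorted(nodes)
    for i, s in enumerate(node_list):
        for t in node_list[i + 1 :]:
            paths = all_shortest_paths(s, t)
            if not paths:
                continue
            frac = 1.0 / len(paths)
            for path in paths:
                for mid in path[1:-1]:
                    node_bc[mid] += frac
                for a, b in zip(path, path[1:]):
                    edge_bc[(min(a, b), max(a, b))] += frac
    return node_bc, edge_bc


def pagerank_linear_solve(nodes, weighted_adjacency, damping=0.85):
    """Exact stationary solution of the damped random walk via linear solve."""
    n = len(nodes)
    index = {node: i for i, node in enumerate(nodes)}
    P = np.zeros((n, n))  # column-stochastic transition matrix
    for u in nodes:
        nbrs = weighted_adjacency[u]
        total = sum(nbrs.values())
        if total == 0:
            P[:, index[u]] = 1.0 / n  # dangling: uniform
        else:
            for v, w in nbrs.items():
                P[index[v], index[u]] = w / total
    A = np.eye(n) - damping * P
    b = np.full(n, (1.0 - damping) / n)
    x = np.linalg.solve(A, b)
    x /= x.sum()
    return {node: x[index[node]] for node in nodes}


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def best_modularity_partition(nodes, edges, gamma=1.0):
    """Exhaustive modularity maximisation over all set partitions.

    ``edges``: list of (u, v, w).  Returns (best partition, best Q).
    Only usable for tiny graphs (Bell(6) = 203 partitions).
    """
    m = sum(w for _, _, w in edges)
    degree = {n: 0.0 for n in nodes}
    for u, v, w in edges:
        degree[u] += w
        degree[v] += w

    def q_of(partition):
        community = {}
        for ci, group in enumerate(partition):
            for node in group:
                community[node] = ci
        e_c = [0.0] * len(partition)
        d_c = [0.0] * len(partition)
        for u, v, w in edges:
            if community[u] == community[v]:
                e_c[community[u]] += w
        for node in nodes:
            d_c[community[node]] += degree[node]
        return sum(
            e / m - gamma * (d / (2 * m)) ** 2 for e, d in zip(e_c, d_c)
        )

    best, best_q = None, -math.inf
    count = 0
    for partition in set_partitions(list(nodes)):
        count += 1
        q = q_of(partition)
        if q > best_q:
            best, best_q = partition, q
    return best, best_q, count


def dense_mcl_clusters(nodes, edges, inflation, max_iter=300, tol=1e-10):
    """Dense-matrix MCL run to convergence without pruning.

    Same model (self-loop = max incident weight, expansion, inflation,
    column renormalisation) but dense numpy throughout and no pruning;
    clusters are connected components of the limit's nonzero structure,
    found by union-find.
    """
    order = sorted(nodes)
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    M = np.zeros((n, n))
    for u, v, w in edges:
        M[index[u], index[v]] = M[index[v], index[u]] = abs(w)
    for i in range(n):
        M[i, i] = M[i].max() if M[i].max() > 0 else 1.0
    M /= M.sum(axis=0)
    for _ in range(max_iter):
        prev = M.copy()
        M = M @ M
        M **= inflation
        M /= M.sum(axis=0)
        if np.abs(M - prev).max() < tol:
            break

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    ii, jj = np.nonzero(M > 1e-8)
    for a, b in zip(ii, jj):
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    groups = {}
    for i, node in enumerate(order):
        groups.setdefault(find(i), []).append(node)
    return sorted((sorted(g) for g in groups.values()), key=lambda g: (-len(g), g[0]))
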