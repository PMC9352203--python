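"""Composable graph transforms: k-NN pruning, filtering, component removal,
edge contraction, and an ordered transform stack.

All transforms are pure: they return a new graph and never modify their
input.  Declarative :class:`TransformSpec` objects (name + parameter map)
drive the stack form used by the CLI and YAML pipelines; the individual
functions also accept arbitrary Python predicates.
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field

from .graph import CATEGORICAL, NUMERIC, TEXT, Graph, edge_key

log = logging.getLogger(__name__)

_OPS = {
    ">": operator.gt,
    ">=": operator.ge,
    "<": operator.lt,
    "<=": operator.le,
    "==": operator.eq,
    "!=": operator.ne,
}


# ---------------------------------------------------------------------------
# k-NN edge pruning


def knn_prune(graph: Graph, k: int, mutual: bool = False) -> Graph:
    """Keep each edge only if it ranks in the top-k weights of an endpoint.

    Default is the union rule: an edge survives when it is among the k
    strongest incident edges of *either* endpoint, which guarantees every
    non-isolated node keeps at least its single strongest edge (so pruning
    never creates isolates).  ``mutual=True`` switches to the stricter
    intersection rule (top-k for both endpoints).  Ties in weight are broken
    by lexicographic edge id for determinism.  The node set is unchanged.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    top: dict[str, set] = {}
    for node in graph.nodes:
        incident = sorted(
            ((v, w) for v, w in graph.adjacency(node).items()),
            key=lambda item: (-item[1], edge_key(node, item[0])),
        )
        top[node] = {edge_key(node, v) for v, _ in incident[:k]}
    out = Graph()
    out.add_nodes(graph.nodes)
    kept = []
    for u, v, w in graph.edges():
        ek = (u, v)
        keep = (ek in top[u]) and (ek in top[v]) if mutual else (
            ek in top[u] or ek in top[v]
        )
        if keep:
            out.add_edge(u, v, w)
            kept.append(ek)
    out.node_attrs = graph.node_attrs.copy()
    out.edge_attrs = graph.edge_attrs.restrict(kept)
    return out


# ---------------------------------------------------------------------------
# filtering


def _edge_value(graph: Graph, u: str, v: str, w: float, attribute: str):
    if attribute == "weight":
        return w
    if attribute not in graph.edge_attrs:
        raise KeyError(f"edge attribute {attribute!r} does not exist")
    return graph.edge_attrs.get(attribute, (u, v))


def filter_edges(graph: Graph, keep, attribute: str = "weight") -> Graph:
    """Remove edges whose ``attribute`` value fails ``keep``; nodes stay.

    ``keep`` is a predicate over the edge's weight (attribute="weight") or
    over a named edge-attribute value.  Nodes left isolated are kept — use
    :func:`filter_nodes` or :func:`remove_components` to drop them.
    """
    out = Graph()
    out.add_nodes(graph.nodes)
    surviving = []
    for u, v, w in graph.edges():
        if keep(_edge_value(graph, u, v, w, attribute)):
            out.add_edge(u, v, w)
            surviving.append((u, v))
    out.node_attrs = graph.node_attrs.copy()
    out.edge_attrs = graph.edge_attrs.restrict(surviving)
    return out


def filter_nodes(graph: Graph, keep, attributes) -> Graph:
    """Remove nodes (and incident edges) failing a predicate over attributes.

    ``attributes`` is one name or a list of names; ``keep`` receives the
    corresponding values positionally.  Values are captured before any
    removal begins, so the result is order-independent and one application
    never cascades (removing a node does not change the Degree another node
    was judged on).  "Degree" is computed on the fly when requested but not
    yet stored.
    """
    if isinstance(attributes, str):
        attributes = [attributes]
    snapshot = graph.copy()
    if "Degree" in attributes and "Degree" not in snapshot.node_attrs:
        snapshot.degree()
    for name in attributes:
        if name not in snapshot.node_attrs:
            raise KeyError(f"node attribute {name!r} does not exist")
    survivors = [
        n
        for n in snapshot.nodes
        if keep(*(snapshot.node_attrs.get(name, n) for name in attributes))
    ]
    return snapshot.subgraph(survivors)


def annotate_max_edge_weight(graph: Graph, name: str = "Max Edge Weight") -> Graph:
    """Store each node's strongest incident edge weight as a node attribute.

    The attribute used by the outlier rule "poorly correlated and poorly
    connected" (max incident r below a cutoff and degree below a cutoff).
    Isolated nodes get a missing value.
    """
    out = graph.copy()
    values = {
        n: (max(out.adjacency(n).values()) if out.adjacency(n) else None)
        for n in out.nodes
    }
    out.node_attrs.set_column(name, NUMERIC, values)
    return out


def remove_components(graph: Graph, min_nodes: int) -> Graph:
    """Delete connected components with fewer than ``min_nodes`` nodes."""
    if min_nodes < 1:
        raise ValueError(f"min_nodes must be >= 1, got {min_nodes}")
    index = graph.components()
    keep: list[str] = []
    for size, members in zip(index.sizes, index.members):
        if size >= min_nodes:
            keep.extend(members)
    return graph.subgraph(keep)


# ---------------------------------------------------------------------------
# edge contraction


def contract_edges(
    graph: Graph,
    keep,
    attribute: str = "weight",
    additive_attrs: tuple = (),
) -> Graph:
    """Contract every edge matching the predicate.

    Contraction is the quotient over connected subgraphs of matching edges:
    each such subgraph merges into one node whose id is the lexicographically
    smallest member id.  Merged nodes carry a text attribute "Members"
    (";"-joined sorted original ids) and a numeric "Member Count".  Parallel
    edges created by the quotient collapse to a single edge keeping the
    maximum weight; self-loops vanish.

    Node attributes merge by taking the smallest-id member's value, except
    numeric columns named in ``additive_attrs`` which are summed (for
    count-like columns).
    """
    parent: dict[str, str] = {n: n for n in graph.nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the lexicographically smaller id as the representative
            if rb < ra:
                ra, rb = rb, ra
            parent[rb] = ra

    for u, v, w in graph.edges():
        if keep(_edge_value(graph, u, v, w, attribute)):
            union(u, v)

    groups: dict[str, list[str]] = {}
    for n in graph.nodes:
        groups.setdefault(find(n), []).append(n)

    out = Graph()
    out.add_nodes(sorted(groups))
    # quotient edges: max weight among parallels, self-loops dropped
    best: dict[tuple, tuple] = {}  # new edge key -> (weight, original edge key)
    for u, v, w in graph.edges():
        nu, nv = find(u), find(v)
        if nu == nv:
            continue
        nk = edge_key(nu, nv)
        ok = edge_key(u, v)
        if nk not in best or (w, ok) > best[nk]:
            best[nk] = (w, ok)
    for (nu, nv), (w, _) in best.items():
        out.add_edge(nu, nv, w)

    # node attributes: smallest-id member wins, additive columns sum
    for name, col in graph.node_attrs.items():
        merged = {}
        for rep, members in groups.items():
            members_sorted = sorted(members)
            if col.kind == NUMERIC and name in additive_attrs:
                vals = [col.values[m] for m in members_sorted if col.values.get(m) is not None]
                if vals:
                    merged[rep] = float(sum(vals))
            else:
                for m in members_sorted:
                    if m in col.values:
                        merged[rep] = col.values[m]
                        break
        out.node_attrs.set_column(name, col.kind, merged)

    out.node_attrs.set_column(
        "Members",
        TEXT,
        {rep: ";".join(sorted(members)) for rep, members in groups.items()},
    )
    out.node_attrs.set_column(
        "Member Count", NUMERIC, {rep: len(members) for rep, members in groups.items()}
    )

    # edge attributes: carried over from the surviving (max-weight) original edge
    for name, col in graph.edge_attrs.items():
        merged = {}
        for nk, (_, ok) in best.items():
            if ok in col.values:
                merged[nk] = col.values[ok]
        out.edge_attrs.set_column(name, col.kind, merged)
    return out


# ---------------------------------------------------------------------------
# declarative transform stack


KNOWN_TRANSFORMS = (
    "knn",
    "filter_edges",
    "filter_nodes",
    "remove_components",
    "contract_edges",
)


@dataclass
class TransformSpec:
    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in KNOWN_TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.name!r}; known: {KNOWN_TRANSFORMS}"
            )
        self.validate()

    def validate(self) -> None:
        p = dict(self.params)
        if self.name == "knn":
            k = p.pop("k", None)
            if not isinstance(k, int) or k < 1:
                raise ValueError("knn requires integer parameter k >= 1")
            p.pop("mutual", None)
        elif self.name in ("filter_edges", "filter_nodes", "contract_edges"):
            if "op" in p and p["op"] not in _OPS:
                raise ValueError(f"unknown comparison op {p['op']!r}")
            if "value" not in p:
                raise ValueError(f"{self.name} requires a 'value' parameter")
            p.pop("attribute", None)
            p.pop("op", None)
            p.pop("value", None)
        elif self.name == "remove_components":
            m = p.pop("min_nodes", None)
            if not isinstance(m, int) or m < 1:
                raise ValueError("remove_components requires integer min_nodes >= 1")
        if p:
            raise ValueError(f"unknown parameters for {self.name}: {sorted(p)}")


def _predicate(params: dict):
    op = _OPS[params.get("op", ">=")]
    value = params["value"]
    return lambda x: x is not None and op(x, value)


def apply_transform(graph: Graph, spec: TransformSpec) -> Graph:
    p = spec.params
    if spec.name == "knn":
        return knn_prune(graph, p["k"], mutual=p.get("mutual", False))
    if spec.name == "filter_edges":
        return filter_edges(graph, _predicate(p), attribute=p.get("attribute", "weight"))
    if spec.name == "filter_nodes":
        return filter_nodes(graph, _predicate(p), p.get("attribute", "Degree"))
    if spec.name == "remove_components":
        return remove_components(graph, p["min_nodes"])
    if spec.name == "contract_edges":
        return contract_edges(graph, _predicate(p), attribute=p.get("attribute", "weight"))
    raise AssertionError(spec.name)


def apply_stack(graph: Graph, specs) -> Graph:
    """Apply an ordered list of TransformSpecs, logging element counts."""
    current = graph
    for spec in specs:
        before = (current.n_nodes, current.n_edges)
        current = apply_transform(current, spec)
        log.info(
            "transform %s: %d nodes, %d edges -> %d nodes, %d edges",
            spec.name,
            *before,
            current.n_nodes,
            current.n_edges,
        )
    return current
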