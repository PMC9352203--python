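"""Core graph model: undirected weighted simple graphs with typed attributes.

The in-memory representation used by every other module.  Nodes are opaque
strings; edges are unordered pairs carrying a single real weight.  Node and
edge metadata live in :class:`AttributeTable` objects whose columns are typed
as ``categorical``, ``numeric`` or ``text``.  Missing numeric values are
represented explicitly (``None``), never as 0, because 0 is a meaningful
value in expression-like data.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

CATEGORICAL = "categorical"
NUMERIC = "numeric"
TEXT = "text"
_KINDS = frozenset({CATEGORICAL, NUMERIC, TEXT})


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered-pair identity for an edge."""
    return (u, v) if u <= v else (v, u)


@dataclass
class AttributeColumn:
    kind: str
    values: dict = field(default_factory=dict)

    def copy(self) -> "AttributeColumn":
        return AttributeColumn(self.kind, dict(self.values))


class AttributeTable:
    """Typed attribute columns keyed by element id (node id or edge key)."""

    def __init__(self) -> None:
        self._columns: dict[str, AttributeColumn] = {}

    def __contains__(self, name: str) -> bool:
        return name in self._columns

    @property
    def names(self) -> list[str]:
        return list(self._columns)

    def kind(self, name: str) -> str:
        return self._columns[name].kind

    def column(self, name: str) -> AttributeColumn:
        try:
            return self._columns[name]
        except KeyError:
            raise KeyError(f"no attribute column named {name!r}") from None

    def ensure(self, name: str, kind: str) -> AttributeColumn:
        if kind not in _KINDS:
            raise ValueError(f"unknown attribute kind {kind!r}")
        col = self._columns.get(name)
        if col is None:
            col = AttributeColumn(kind)
            self._columns[name] = col
        elif col.kind != kind:
            raise ValueError(
                f"attribute {name!r} already exists with kind {col.kind!r}"
            )
        return col

    def set_column(self, name: str, kind: str, values: Mapping) -> None:
        """Create or replace a whole column."""
        if kind not in _KINDS:
            raise ValueError(f"unknown attribute kind {kind!r}")
        vals = dict(values)
        if kind == NUMERIC:
            for k, v in vals.items():
                if v is not None:
                    v = float(v)
                    if not math.isfinite(v):
                        raise ValueError(
                            f"non-finite numeric attribute {name!r} for {k!r}"
                        )
                    vals[k] = v
        self._columns[name] = AttributeColumn(kind, vals)

    def set_value(self, name: str, element, value) -> None:
        self.column(name).values[element] = value

    def get(self, name: str, element, default=None):
        col = self._columns.get(name)
        if col is None:
            return default
        return col.values.get(element, default)

    def drop_column(self, name: str) -> None:
        self._columns.pop(name, None)

    def restrict(self, elements: Iterable) -> "AttributeTable":
        """Table restricted to the given elements (used after transforms)."""
        keep = set(elements)
        out = AttributeTable()
        for name, col in self._columns.items():
            out._columns[name] = AttributeColumn(
                col.kind, {k: v for k, v in col.values.items() if k in keep}
            )
        return out

    def copy(self) -> "AttributeTable":
        out = AttributeTable()
        for name, col in self._columns.items():
            out._columns[name] = col.copy()
        return out

    def items(self) -> Iterator[tuple[str, AttributeColumn]]:
        return iter(self._columns.items())


@dataclass(frozen=True)
class ComponentIndex:
    """Connected-component partition, ranked by size (rank 0 = largest).

    Ties in size are broken by the lexicographically smallest member id, so
    ranks are deterministic regardless of insertion order.
    """

    component_of: dict
    sizes: list
    members: list  # members[rank] = sorted list of node ids

    @property
    def n_components(self) -> int:
        return len(self.sizes)


class Graph:
    """Undirected weighted simple graph with stable string node ids."""

    def __init__(self) -> None:
        self._adj: dict[str, dict[str, float]] = {}
        self.node_attrs = AttributeTable()
        self.edge_attrs = AttributeTable()

    # -- construction -------------------------------------------------

    def add_node(self, node: str) -> "Graph":
        node = str(node)
        if node not in self._adj:
            self._adj[node] = {}
        return self

    def add_nodes(self, nodes: Iterable[str]) -> "Graph":
        for n in nodes:
            self.add_node(n)
        return self

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> "Graph":
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop rejected: {u!r}")
        w = float(weight)
        if not math.isfinite(w):
            raise ValueError(f"non-finite edge weight on ({u!r}, {v!r})")
        self.add_node(u)
        self.add_node(v)
        # re-adding an existing edge replaces its weight
        self._adj[u][v] = w
        self._adj[v][u] = w
        return self

    def add_edges(self, items: Iterable) -> "Graph":
        for item in items:
            if len(item) == 2:
                u, v = item
                self.add_edge(u, v)
            else:
                u, v, w = item[:3]
                self.add_edge(u, v, w)
        return self

    def remove_edge(self, u: str, v: str) -> None:
        del self._adj[u][v]
        del self._adj[v][u]
        k = edge_key(u, v)
        for _, col in self.edge_attrs.items():
            col.values.pop(k, None)

    def remove_node(self, node: str) -> None:
        for nbr in list(self._adj[node]):
            self.remove_edge(node, nbr)
        del self._adj[node]
        for _, col in self.node_attrs.items():
            col.values.pop(node, None)

    # -- inspection ---------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self._adj)

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Iterate (u, v, weight) with u <= v, each edge once."""
        for u, nbrs in self._adj.items():
            for v, w in nbrs.items():
                if u <= v:
                    yield u, v, w

    def edge_keys(self) -> list[tuple[str, str]]:
        return [(u, v) for u, v, _ in self.edges()]

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, {})

    def weight(self, u: str, v: str) -> float:
        return self._adj[u][v]

    def neighbors(self, node: str) -> list[str]:
        return list(self._adj[node])

    def adjacency(self, node: str) -> dict[str, float]:
        return self._adj[node]

    def degree_of(self, node: str) -> int:
        return len(self._adj[node])

    def copy(self) -> "Graph":
        g = Graph()
        for n in self._adj:
            g._adj[n] = dict(self._adj[n])
        g.node_attrs = self.node_attrs.copy()
        g.edge_attrs = self.edge_attrs.copy()
        return g

    def subgraph(self, nodes: Iterable[str]) -> "Graph":
        keep = set(nodes)
        g = Graph()
        for n in self._adj:
            if n in keep:
                g._adj[n] = {v: w for v, w in self._adj[n].items() if v in keep}
        g.node_attrs = self.node_attrs.restrict(g._adj)
        g.edge_attrs = self.edge_attrs.restrict(
            [edge_key(u, v) for u, v, _ in g.edges()]
        )
        return g

    # -- analysis -----------------------------------------------------

    def components(self) -> ComponentIndex:
        """Partition into connected components, largest first.

        Size ties are broken by the smallest member id so that the ranking
        is independent of node/edge insertion order.
        """
        seen: set[str] = set()
        comps: list[list[str]] = []
        for start in self._adj:
            if start in seen:
                continue
            queue = deque([start])
            seen.add(start)
            comp = []
            while queue:
                u = queue.popleft()
                comp.append(u)
                for v in self._adj[u]:
                    if v not in seen:
                        seen.add(v)
                        queue.append(v)
            comps.append(sorted(comp))
        comps.sort(key=lambda c: (-len(c), c[0]))
        component_of = {}
        for rank, comp in enumerate(comps):
            for n in comp:
                component_of[n] = rank
        return ComponentIndex(
            component_of=component_of,
            sizes=[len(c) for c in comps],
            members=comps,
        )

    def degree(self) -> dict[str, int]:
        """Unweighted degree per node, stored as node attribute "Degree"."""
        deg = {n: len(nbrs) for n, nbrs in self._adj.items()}
        self.node_attrs.set_column("Degree", NUMERIC, deg)
        return deg

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
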