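"""Graph readers and writers: GML, GraphML, JSON-graph, edge list, adjacency.

All writers produce files that read back to an identical graph (node set,
edge set, weights to better than 1e-6, attributes up to stringification).
Directed edges in input files are folded to undirected, keeping the maximum
weight when both directions occur.

Formats deliberately not implemented (BioPAX OWL, CX/CX2, MATLAB .mat,
Excel, DOT) raise :class:`UnsupportedFormatError` with a clear message.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from pathlib import Path

import numpy as np
from lxml import etree

from .graph import CATEGORICAL, NUMERIC, TEXT, Graph, edge_key

log = logging.getLogger(__name__)

GML = "gml"
GRAPHML = "graphml"
JSON_GRAPH = "json"
EDGE_LIST = "edgelist"
ADJACENCY = "adjacency"

FORMATS = (GML, GRAPHML, JSON_GRAPH, EDGE_LIST, ADJACENCY)

_UNSUPPORTED = {
    ".owl": "BioPAX OWL",
    ".cx": "CX",
    ".cx2": "CX2",
    ".mat": "MATLAB",
    ".xlsx": "Excel",
    ".xls": "Excel",
    ".dot": "DOT",
    ".gv": "DOT",
}

_EXTENSIONS = {
    ".gml": GML,
    ".graphml": GRAPHML,
    ".json": JSON_GRAPH,
    ".tsv": EDGE_LIST,
    ".csv": EDGE_LIST,
    ".txt": EDGE_LIST,
    ".edges": EDGE_LIST,
}


class UnsupportedFormatError(ValueError):
    pass


class GraphParseError(ValueError):
    pass


def detect_format(path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in _UNSUPPORTED:
        raise UnsupportedFormatError(
            f"{_UNSUPPORTED[suffix]} files are not supported; "
            f"supported formats: {', '.join(FORMATS)}"
        )
    try:
        return _EXTENSIONS[suffix]
    except KeyError:
        raise UnsupportedFormatError(
            f"cannot infer graph format from {path!r}; "
            f"supported formats: {', '.join(FORMATS)}"
        ) from None


def _fold_edge(graph: Graph, u: str, v: str, w: float) -> None:
    """Add an edge, keeping the maximum weight on duplicates."""
    if u == v:
        log.warning("ignoring self-loop on %r", u)
        return
    if graph.has_edge(u, v):
        w = max(w, graph.weight(u, v))
    graph.add_edge(u, v, w)


# ---------------------------------------------------------------------------
# GML


_GML_TOKEN = re.compile(r'"[^"]*"|\[|\]|[^\s\[\]]+')


def _gml_tokens(text: str):
    for match in _GML_TOKEN.finditer(text):
        yield match.group(0)


def _gml_parse_value(tokens):
    tok = next(tokens)
    if tok == "[":
        record = []
        while True:
            key = next(tokens, None)
            if key is None:
                raise GraphParseError("GML: unexpected end of file inside [ ]")
            if key == "]":
                return record
            record.append((key, _gml_parse_value(tokens)))
    if tok.startswith('"'):
        return tok[1:-1]
    try:
        return int(tok)
    except ValueError:
        pass
    try:
        return float(tok)
    except ValueError:
        return tok


def _gml_get(record: list, key: str, default=None):
    for k, v in record:
        if k == key:
            return v
    return default


def read_gml(path) -> Graph:
    text = Path(path).read_text()
    tokens = _gml_tokens(text)
    top = []
    while True:
        key = next(tokens, None)
        if key is None:
            break
        top.append((key, _gml_parse_value(tokens)))
    graph_rec = _gml_get(top, "graph")
    if graph_rec is None:
        raise GraphParseError(f"{path}: no 'graph [ ... ]' record found")

    graph = Graph()
    id_to_node: dict = {}
    for key, value in graph_rec:
        if key != "node":
            continue
        gml_id = _gml_get(value, "id")
        if gml_id is None:
            raise GraphParseError(f"{path}: node record without id")
        label = _gml_get(value, "label")
        node = str(label) if label is not None else str(gml_id)
        id_to_node[gml_id] = node
        graph.add_node(node)
        for k, v in value:
            if k in ("id", "label"):
                continue
            _set_attr(graph.node_attrs, k, node, v)
    for key, value in graph_rec:
        if key != "edge":
            continue
        source = _gml_get(value, "source")
        target = _gml_get(value, "target")
        if source is None or target is None:
            raise GraphParseError(f"{path}: edge record missing source/target")
        try:
            u, v = id_to_node[source], id_to_node[target]
        except KeyError as exc:
            raise GraphParseError(
                f"{path}: edge references unknown node id {exc.args[0]}"
            ) from None
        weight = _gml_get(value, "value")
        if weight is None:
            weight = _gml_get(value, "weight", 1.0)
        _fold_edge(graph, u, v, float(weight))
        for k, val in value:
            if k in ("source", "target", "value", "weight"):
                continue
            _set_attr(graph.edge_attrs, k, edge_key(u, v), val)
    return graph


def _set_attr(table, name, element, value) -> None:
    kind = NUMERIC if isinstance(value, (int, float)) else CATEGORICAL
    if name in table and table.kind(name) != kind:
        value = str(value)  # mixed types: fall back to the existing kind
        kind = table.kind(name)
        if kind == NUMERIC:
            try:
                value = float(value)
            except ValueError:
                return
    table.ensure(name, kind)
    table.set_value(name, element, float(value) if kind == NUMERIC else str(value))


_GML_KEY = re.compile(r"[A-Za-z][A-Za-z0-9]*$")


def _gml_safe_key(name: str) -> str:
    if _GML_KEY.match(name):
        return name
    safe = re.sub(r"[^A-Za-z0-9]", "", name) or "attr"
    if not safe[0].isalpha():
        safe = "a" + safe
    log.warning("GML: attribute name %r written as %r", name, safe)
    return safe


def _gml_value(value) -> str:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return repr(value)
    return '"' + str(value).replace('"', "'") + '"'


def write_gml(graph: Graph, path) -> None:
    node_index = {n: i for i, n in enumerate(graph.nodes)}
    lines = ["graph [", "  directed 0"]
    for node in graph.nodes:
        lines.append("  node [")
        lines.append(f"    id {node_index[node]}")
        lines.append(f'    label "{node}"')
        for name, col in graph.node_attrs.items():
            if node in col.values and col.values[node] is not None:
                lines.append(
                    f"    {_gml_safe_key(name)} {_gml_value(col.values[node])}"
                )
        lines.append("  ]")
    for u, v, w in graph.edges():
        lines.append("  edge [")
        lines.append(f"    source {node_index[u]}")
        lines.append(f"    target {node_index[v]}")
        lines.append(f"    value {w!r}")
        for name, col in graph.edge_attrs.items():
            val = col.values.get((u, v))
            if val is not None:
                lines.append(f"    {_gml_safe_key(name)} {_gml_value(val)}")
        lines.append("  ]")
    lines.append("]")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# GraphML


_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"


def write_graphml(graph: Graph, path) -> None:
    nsmap = {None: _GRAPHML_NS}
    root = etree.Element("graphml", nsmap=nsmap)

    def declare_key(key_id, domain, name, attr_type):
        key = etree.SubElement(root, "key", id=key_id)
        key.set("for", domain)
        key.set("attr.name", name)
        key.set("attr.type", attr_type)

    node_keys, edge_keys = {}, {}
    for i, (name, col) in enumerate(graph.node_attrs.items()):
        kid = f"dn{i}"
        node_keys[name] = (kid, col.kind)
        declare_key(kid, "node", name, "double" if col.kind == NUMERIC else "string")
    declare_key("ew", "edge", "weight", "double")
    for i, (name, col) in enumerate(graph.edge_attrs.items()):
        kid = f"de{i}"
        edge_keys[name] = (kid, col.kind)
        declare_key(kid, "edge", name, "double" if col.kind == NUMERIC else "string")

    gelem = etree.SubElement(root, "graph", id="G", edgedefault="undirected")
    for node in graph.nodes:
        nelem = etree.SubElement(gelem, "node", id=node)
        for name, col in graph.node_attrs.items():
            val = col.values.get(node)
            if val is not None:
                data = etree.SubElement(nelem, "data", key=node_keys[name][0])
                data.text = repr(val) if isinstance(val, float) else str(val)
    for u, v, w in graph.edges():
        eelem = etree.SubElement(gelem, "edge", source=u, target=v)
        data = etree.SubElement(eelem, "data", key="ew")
        data.text = repr(w)
        for name, col in graph.edge_attrs.items():
            val = col.values.get((u, v))
            if val is not None:
                data = etree.SubElement(eelem, "data", key=edge_keys[name][0])
                data.text = repr(val) if isinstance(val, float) else str(val)
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


def read_graphml(path) -> Graph:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GraphParseError(f"{path}: {exc}") from None
    root = tree.getroot()
    ns = {"g": _GRAPHML_NS} if root.tag.startswith("{") else None
    prefix = "g:" if ns else ""

    keys = {}
    for key in root.findall(f"{prefix}key", ns):
        keys[key.get("id")] = (
            key.get("for", "all"),
            key.get("attr.name", key.get("id")),
            key.get("attr.type", "string"),
        )

    graph = Graph()
    gelem = root.find(f"{prefix}graph", ns)
    if gelem is None:
        raise GraphParseError(f"{path}: no <graph> element")
    for nelem in gelem.findall(f"{prefix}node", ns):
        node = nelem.get("id")
        graph.add_node(node)
        for data in nelem.findall(f"{prefix}data", ns):
            _, name, attr_type = keys.get(data.get("key"), ("node", data.get("key"), "string"))
            value = data.text or ""
            if attr_type in ("double", "float", "int", "long"):
                _set_attr(graph.node_attrs, name, node, float(value))
            else:
                _set_attr(graph.node_attrs, name, node, value)
    for eelem in gelem.findall(f"{prefix}edge", ns):
        u, v = eelem.get("source"), eelem.get("target")
        if u not in graph or v not in graph:
            raise GraphParseError(f"{path}: edge references unknown node {u!r}/{v!r}")
        weight = 1.0
        attrs = []
        for data in eelem.findall(f"{prefix}data", ns):
            _, name, attr_type = keys.get(data.get("key"), ("edge", data.get("key"), "string"))
            value = data.text or ""
            if name == "weight":
                weight = float(value)
            elif attr_type in ("double", "float", "int", "long"):
                attrs.append((name, float(value)))
            else:
                attrs.append((name, value))
        _fold_edge(graph, u, v, weight)
        for name, value in attrs:
            _set_attr(graph.edge_attrs, name, edge_key(u, v), value)
    return graph


# ---------------------------------------------------------------------------
# JSON graph


def write_json_graph(graph: Graph, path) -> None:
    nodes = []
    for node in graph.nodes:
        metadata = {
            name: col.values[node]
            for name, col in graph.node_attrs.items()
            if col.values.get(node) is not None
        }
        entry = {"id": node}
        if metadata:
            entry["metadata"] = metadata
        nodes.append(entry)
    edges = []
    for u, v, w in graph.edges():
        metadata = {"weight": w}
        for name, col in graph.edge_attrs.items():
            val = col.values.get((u, v))
            if val is not None:
                metadata[name] = val
        edges.append({"source": u, "target": v, "metadata": metadata})
    Path(path).write_text(
        json.dumps({"nodes": nodes, "edges": edges}, indent=1) + "\n"
    )


def read_json_graph(path) -> Graph:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise GraphParseError(f"{path}: {exc}") from None
    if "graph" in doc and isinstance(doc["graph"], dict):
        doc = doc["graph"]
    graph = Graph()
    for entry in doc.get("nodes", []):
        node = str(entry["id"])
        graph.add_node(node)
        for name, value in (entry.get("metadata") or {}).items():
            _set_attr(graph.node_attrs, name, node, value)
    for entry in doc.get("edges", doc.get("links", [])):
        u, v = str(entry["source"]), str(entry["target"])
        if u not in graph:
            graph.add_node(u)
        if v not in graph:
            graph.add_node(v)
        metadata = dict(entry.get("metadata") or {})
        weight = float(metadata.pop("weight", entry.get("weight", 1.0)))
        _fold_edge(graph, u, v, weight)
        for name, value in metadata.items():
            _set_attr(graph.edge_attrs, name, edge_key(u, v), value)
    return graph


# ---------------------------------------------------------------------------
# edge list


def _delimiter_for(path, delimiter):
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def write_edge_list(graph: Graph, path, delimiter: str | None = None) -> None:
    delimiter = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        for u, v, w in graph.edges():
            fh.write(f"{u}{delimiter}{v}{delimiter}{w!r}\n")
    if graph.node_attrs.names or graph.edge_attrs.names:
        log.warning("edge list carries no attributes; attribute columns dropped")
    isolated = [n for n in graph.nodes if graph.degree_of(n) == 0]
    if isolated:
        log.warning("edge list cannot represent %d isolated nodes", len(isolated))


def read_edge_list(path, delimiter: str | None = None) -> Graph:
    delimiter = _delimiter_for(path, delimiter)
    graph = Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter)
            if len(parts) not in (2, 3):
                raise GraphParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            u, v = parts[0].strip(), parts[1].strip()
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise GraphParseError(
                        f"{path}:{lineno}: non-numeric weight {parts[2]!r}"
                    ) from None
            else:
                w = 1.0
            _fold_edge(graph, u, v, w)
    return graph


# ---------------------------------------------------------------------------
# adjacency matrix


def write_adjacency(graph: Graph, path, delimiter: str = ",") -> None:
    nodes = graph.nodes
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow([""] + nodes)
        for u in nodes:
            row = [u]
            for v in nodes:
                row.append(repr(graph.weight(u, v)) if graph.has_edge(u, v) else "0")
            writer.writerow(row)


def read_adjacency(path, delimiter: str = ",", tol: float = 1e-9) -> Graph:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        raise GraphParseError(f"{path}: empty file")
    col_ids = [c.strip() for c in rows[0][1:]]
    row_ids = []
    values = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        row_ids.append(row[0].strip())
        try:
            values.append([float(c) for c in row[1:]])
        except ValueError as exc:
            raise GraphParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    matrix = np.array(values, dtype=float)
    if matrix.shape[0] != matrix.shape[1] or row_ids != col_ids:
        raise GraphParseError(
            f"{path}: adjacency matrix must be square with matching "
            f"row/column ids ({matrix.shape[0]} rows x {matrix.shape[1]} cols)"
        )
    asym = np.abs(matrix - matrix.T)
    np.fill_diagonal(asym, 0.0)
    if asym.max() > tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise GraphParseError(
            f"{path}: asymmetric adjacency at ({row_ids[i]}, {col_ids[j]}): "
            f"{matrix[i, j]!r} vs {matrix[j, i]!r}"
        )
    graph = Graph()
    graph.add_nodes(row_ids)
    n = len(row_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if matrix[i, j] != 0.0:
                graph.add_edge(row_ids[i], row_ids[j], matrix[i, j])
    return graph


# ---------------------------------------------------------------------------
# dispatch


_READERS = {
    GML: read_gml,
    GRAPHML: read_graphml,
    JSON_GRAPH: read_json_graph,
    EDGE_LIST: read_edge_list,
    ADJACENCY: read_adjacency,
}
_WRITERS = {
    GML: write_gml,
    GRAPHML: write_graphml,
    JSON_GRAPH: write_json_graph,
    EDGE_LIST: write_edge_list,
    ADJACENCY: write_adjacency,
}


def read_graph(path, fmt: str | None = None, **options) -> Graph:
    """Read a graph, inferring the format from the extension when not given."""
    fmt = fmt or detect_format(path)
    if fmt not in _READERS:
        raise UnsupportedFormatError(
            f"unknown format {fmt!r}; supported: {', '.join(FORMATS)}"
        )
    return _READERS[fmt](path, **options)


def write_graph(graph: Graph, path, fmt: str | None = None, **options) -> None:
    fmt = fmt or detect_format(path)
    if fmt not in _WRITERS:
        raise UnsupportedFormatError(
            f"unknown format {fmt!r}; supported: {', '.join(FORMATS)}"
        )
    _WRITERS[fmt](graph, path, **options)
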