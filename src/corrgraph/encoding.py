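"""Attribute-to-visual mapping: colour and size channels from attributes.

Categorical attributes get palette colours assigned by value frequency;
numeric attributes map affinely onto an interpolated colour ramp and a size
range.  Encodings are written back onto the graph as ``colour`` (hex) and
``size`` (real) attributes so any downstream renderer can consume them from
GraphML/JSON output.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .graph import CATEGORICAL, NUMERIC, TEXT, Graph

log = logging.getLogger(__name__)

# 20 maximally-distinct colours (Kelly-style ordering)
DEFAULT_PALETTE = (
    "#e6194b", "#3cb44b", "#ffe119", "#4363d8", "#f58231",
    "#911eb4", "#46f0f0", "#f032e6", "#bcf60c", "#fabebe",
    "#008080", "#e6beff", "#9a6324", "#fffac8", "#800000",
    "#aaffc3", "#808000", "#ffd8b1", "#000075", "#808080",
)
MISSING_COLOUR = "#bfbfbf"  # neutral grey for missing values

WHITE_RED = ("#ffffff", "#ff0000")


def _hex_to_rgb(colour: str) -> tuple[int, int, int]:
    colour = colour.lstrip("#")
    return tuple(int(colour[i : i + 2], 16) for i in (0, 2, 4))


def _rgb_to_hex(rgb) -> str:
    return "#{:02x}{:02x}{:02x}".format(*(int(round(c)) for c in rgb))


def interpolate_colour(ramp: tuple[str, str], t: float) -> str:
    """Linear sRGB interpolation between the two ramp endpoints."""
    a = _hex_to_rgb(ramp[0])
    b = _hex_to_rgb(ramp[1])
    return _rgb_to_hex(tuple(a_c + t * (b_c - a_c) for a_c, b_c in zip(a, b)))


@dataclass
class VisualEncoding:
    scope: str  # "nodes" | "edges"
    channel: str  # "colour" | "size"
    attribute: str
    colour_of: dict = field(default_factory=dict)  # element -> hex colour
    size_of: dict = field(default_factory=dict)  # element -> real size
    legend: dict = field(default_factory=dict)  # category -> colour (categorical)


def _elements(graph: Graph, scope: str):
    if scope == "nodes":
        return graph.nodes, graph.node_attrs
    if scope == "edges":
        return graph.edge_keys(), graph.edge_attrs
    raise ValueError(f"scope must be 'nodes' or 'edges', got {scope!r}")


def encode_categorical(
    graph: Graph,
    attribute: str,
    scope: str = "nodes",
    palette: tuple = DEFAULT_PALETTE,
) -> VisualEncoding:
    """Assign one palette colour per category.

    Categories are ordered by descending frequency (ties lexicographic) and
    take palette colours in that order; with more categories than colours
    the palette cycles and a warning is logged.  Missing values get a
    neutral grey.
    """
    elements, attrs = _elements(graph, scope)
    if attribute not in attrs:
        raise KeyError(f"{scope[:-1]} attribute {attribute!r} does not exist")
    if attrs.kind(attribute) == NUMERIC:
        raise TypeError(
            f"attribute {attribute!r} is numeric; use encode_numeric for spectra"
        )
    values = [attrs.get(attribute, e) for e in elements]
    counts = Counter(v for v in values if v is not None)
    ordered = sorted(counts, key=lambda v: (-counts[v], str(v)))
    if len(ordered) > len(palette):
        log.warning(
            "%d categories exceed the %d-colour palette; colours will cycle",
            len(ordered),
            len(palette),
        )
    legend = {v: palette[i % len(palette)] for i, v in enumerate(ordered)}
    colour_of = {
        e: (legend[v] if v is not None else MISSING_COLOUR)
        for e, v in zip(elements, values)
    }
    return VisualEncoding(scope, "colour", attribute, colour_of=colour_of, legend=legend)


def encode_numeric(
    graph: Graph,
    attribute: str,
    scope: str = "nodes",
    ramp: tuple[str, str] = WHITE_RED,
    sizes: tuple[float, float] = (0.5, 2.0),
) -> VisualEncoding:
    """Map a numeric attribute onto a colour ramp and size range.

    A value v maps to t = (v - min) / (max - min), clamped to [0, 1]
    (t = 0.5 when the attribute is constant); colour interpolates linearly
    along ``ramp`` and size is s_min + t * (s_max - s_min).  Missing values
    get the neutral grey and the minimum size.
    """
    elements, attrs = _elements(graph, scope)
    if attribute not in attrs:
        raise KeyError(f"{scope[:-1]} attribute {attribute!r} does not exist")
    if attrs.kind(attribute) != NUMERIC:
        raise TypeError(
            f"attribute {attribute!r} is {attrs.kind(attribute)}; "
            "use encode_categorical"
        )
    values = {e: attrs.get(attribute, e) for e in elements}
    present = [v for v in values.values() if v is not None]
    if not present:
        raise ValueError(f"attribute {attribute!r} has no non-missing values")
    lo, hi = min(present), max(present)
    span = hi - lo
    s_min, s_max = sizes

    colour_of, size_of = {}, {}
    for e, v in values.items():
        if v is None:
            colour_of[e] = MISSING_COLOUR
            size_of[e] = s_min
            continue
        t = 0.5 if span == 0 else min(1.0, max(0.0, (v - lo) / span))
        colour_of[e] = interpolate_colour(ramp, t)
        size_of[e] = s_min + t * (s_max - s_min)
    return VisualEncoding(scope, "colour+size", attribute, colour_of, size_of)


def apply_encoding(graph: Graph, encoding: VisualEncoding) -> None:
    """Bake an encoding into ``colour``/``size`` attribute columns."""
    attrs = graph.node_attrs if encoding.scope == "nodes" else graph.edge_attrs
    if encoding.colour_of:
        attrs.set_column("colour", TEXT, encoding.colour_of)
    if encoding.size_of:
        attrs.set_column("size", NUMERIC, encoding.size_of)
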