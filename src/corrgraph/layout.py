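"""Seeded force-directed layout in 2D/3D with concentric component packing.

Each connected component is laid out independently by a spring embedder
(repulsion between all node pairs approximated with a Barnes-Hut tree,
attraction along edges proportional to distance and edge weight), then the
components are arranged in concentric rings around the largest one,
large-to-small, with guaranteed non-overlapping bounding volumes.

The layout is static (run to convergence) rather than continuously animated;
:func:`spring_step` exposes the iteration so callers can drive it
incrementally if they want live unfolding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .graph import Graph

IDEAL_EDGE_LENGTH = 1.0  # spring rest length for unit-weight edges
NODE_RADIUS = 0.5  # display radius used for bounding volumes
COOLING = 0.95  # per-iteration decay of the displacement cap
STEP_SCALE = 0.1  # fraction of the net force applied per iteration
THETA = 0.8  # Barnes-Hut opening angle


@dataclass
class LayoutResult:
    coords: dict  # node-id -> ndarray of length dims
    dims: int
    component_offsets: dict  # component rank -> (centre ndarray, bounding radius)
    converged: bool
    iterations_run: int


# ---------------------------------------------------------------------------
# Barnes-Hut tree (2^dims-ary: quadtree in 2D, octree in 3D)


class _BHNode:
    __slots__ = ("centre", "half", "mass", "com", "children", "index")

    def __init__(self, centre, half):
        self.centre = centre
        self.half = half
        self.mass = 0.0
        self.com = np.zeros_like(centre)
        self.children = None
        self.index = -1  # particle index when leaf with one body


def _bh_build(pos: np.ndarray) -> _BHNode:
    lo = pos.min(axis=0)
    hi = pos.max(axis=0)
    centre = (lo + hi) / 2.0
    half = float(max((hi - lo).max() / 2.0, 1e-9)) * 1.001
    root = _BHNode(centre, half)
    for i in range(len(pos)):
        _bh_insert(root, pos, i)
    return root


def _bh_insert(node: _BHNode, pos: np.ndarray, i: int, depth: int = 0) -> None:
    p = pos[i]
    if node.mass == 0.0:
        node.mass = 1.0
        node.com = p.copy()
        node.index = i
        return
    if node.children is None:
        if depth > 48:  # coincident points: merge into one body
            node.com = (node.com * node.mass + p) / (node.mass + 1.0)
            node.mass += 1.0
            return
        old = node.index
        node.children = {}
        node.index = -1
        _bh_insert(_bh_child(node, pos[old]), pos, old, depth + 1)
    _bh_insert(_bh_child(node, p), pos, i, depth + 1)
    node.com = (node.com * node.mass + p) / (node.mass + 1.0)
    node.mass += 1.0


def _bh_child(node: _BHNode, p: np.ndarray) -> _BHNode:
    key = 0
    for d in range(len(p)):
        if p[d] >= node.centre[d]:
            key |= 1 << d
    child = node.children.get(key)
    if child is None:
        offset = np.array(
            [node.half / 2.0 if (key >> d) & 1 else -node.half / 2.0 for d in range(len(p))]
        )
        child = _BHNode(node.centre + offset, node.half / 2.0)
        node.children[key] = child
    return child


def _bh_force(node: _BHNode, p: np.ndarray, i: int, k2: float) -> np.ndarray:
    """Repulsive force k^2/d on particle i from the tree rooted at node."""
    force = np.zeros_like(p)
    stack = [node]
    while stack:
        cell = stack.pop()
        if cell.mass == 0.0:
            continue
        if cell.children is None and cell.index == i and cell.mass == 1.0:
            continue
        diff = p - cell.com
        d = float(np.linalg.norm(diff))
        if cell.children is None or (cell.half * 2.0) / max(d, 1e-12) < THETA:
            mass = cell.mass
            if cell.children is None and cell.index == i:
                mass -= 1.0  # self-contribution inside a merged leaf
            if mass <= 0.0:
                continue
            if d < 1e-9:
                # coincident: deterministic tiny kick along first axis
                diff = np.zeros_like(p)
                diff[0] = 1e-4
                d = 1e-4
            force += mass * k2 / (d * d) * diff
        else:
            stack.extend(cell.children.values())
    return force


# ---------------------------------------------------------------------------
# spring embedder


def spring_step(
    pos: np.ndarray, edges: list, temperature: float
) -> tuple[np.ndarray, float]:
    """One force iteration; returns new positions and mean applied displacement.

    ``edges`` is a list of (i, j, weight) index triples.  Repulsion between
    all pairs is k^2/d (Barnes-Hut, theta=0.8); attraction along edges is
    w * d, giving a rest length of k/sqrt(w) for an isolated pair.
    """
    n = len(pos)
    k2 = IDEAL_EDGE_LENGTH * IDEAL_EDGE_LENGTH
    forces = np.zeros_like(pos)
    if n > 1:
        root = _bh_build(pos)
        for i in range(n):
            forces[i] += _bh_force(root, pos[i], i, k2)
    for i, j, w in edges:
        diff = pos[j] - pos[i]
        d = float(np.linalg.norm(diff))
        if d < 1e-12:
            continue
        pull = w * d * (diff / d)
        forces[i] += pull
        forces[j] -= pull

    step = STEP_SCALE * forces
    norms = np.linalg.norm(step, axis=1)
    over = norms > temperature
    if over.any():
        step[over] *= (temperature / norms[over])[:, None]
    new_pos = pos + step
    applied = float(np.linalg.norm(step, axis=1).mean()) if n else 0.0
    return new_pos, applied


def _layout_component(
    nodes: list, edges: list, dims: int, rng: np.random.Generator,
    max_iter: int, tol: float,
) -> tuple[np.ndarray, bool, int]:
    n = len(nodes)
    pos = rng.uniform(-0.5, 0.5, size=(n, dims))
    if n == 1:
        return np.zeros((1, dims)), True, 0
    temperature = 0.5
    converged = False
    iterations = 0
    window = 25  # stiff graphs settle into a tiny limit cycle; judge net drift
    anchor = pos.copy()
    for iterations in range(1, max_iter + 1):
        pos, applied = spring_step(pos, edges, temperature)
        temperature = max(temperature * COOLING, 0.005)
        if applied < tol * IDEAL_EDGE_LENGTH:
            converged = True
            break
        if iterations % window == 0:
            drift = float(np.linalg.norm(pos - anchor, axis=1).mean()) / window
            if drift < tol * IDEAL_EDGE_LENGTH:
                converged = True
                break
            anchor = pos.copy()
    pos -= pos.mean(axis=0)  # centre on the component centroid
    return pos, converged, iterations


def force_layout(
    graph: Graph,
    dims: int = 3,
    seed: int = 1,
    max_iter: int = 2000,
    tol: float = 1e-3,
) -> LayoutResult:
    """Force-directed layout of every component plus concentric arrangement.

    Deterministic for a fixed seed: positions are initialised uniformly at
    random in the unit cube from a generator derived from ``seed`` and the
    component rank, and every subsequent operation is deterministic.  Always
    returns; ``converged`` is False for components that hit ``max_iter``.
    """
    if dims not in (2, 3):
        raise ValueError(f"dims must be 2 or 3, got {dims}")
    index = graph.components()
    per_component = []
    all_converged = True
    total_iterations = 0
    for rank, members in enumerate(index.members):
        sub_index = {n: i for i, n in enumerate(members)}
        edges = [
            (sub_index[u], sub_index[v], w)
            for u, v, w in graph.edges()
            if u in sub_index and v in sub_index
        ]
        rng = np.random.default_rng([seed, rank])
        pos, converged, iters = _layout_component(
            members, edges, dims, rng, max_iter, tol
        )
        all_converged = all_converged and converged
        total_iterations += iters
        radius = float(np.linalg.norm(pos, axis=1).max()) + NODE_RADIUS if len(pos) else NODE_RADIUS
        per_component.append(
            LayoutResult(
                coords={n: pos[i] for i, n in enumerate(members)},
                dims=dims,
                component_offsets={rank: (np.zeros(dims), radius)},
                converged=converged,
                iterations_run=iters,
            )
        )
    result = arrange_components(per_component)
    result.converged = all_converged
    result.iterations_run = total_iterations
    return result


def arrange_components(results: list) -> LayoutResult:
    """Place per-component layouts in concentric rings, large-to-small.

    The rank-0 (largest) component sits at the origin; later components fill
    rings of increasing radius in rank order, a new ring starting whenever
    the current one is full.  Bounding spheres never overlap: adjacent
    placements are separated by at least the sum of their radii plus 10% of
    the larger radius.
    """
    if not results:
        return LayoutResult({}, 3, {}, True, 0)
    dims = results[0].dims
    radii = [next(iter(r.component_offsets.values()))[1] for r in results]

    centres: list[np.ndarray] = [np.zeros(dims)]
    outer = radii[0]
    i = 1
    while i < len(results):
        # collect the next ring greedily
        ring: list[int] = []
        ring_max = 0.0
        ring_R = 0.0
        while i < len(results):
            r = radii[i]
            cand_max = max(ring_max, r)
            cand_R = outer + 1.1 * cand_max + 0.1 * max(radii[: i + 1])
            gap = 2.2 * cand_max  # adjacent separation with 10% padding
            ratio = min(1.0, gap / (2.0 * cand_R))
            needed = (len(ring) + 1) * 2.0 * math.asin(ratio)
            if ring and needed > 2.0 * math.pi:
                break
            ring.append(i)
            ring_max = cand_max
            ring_R = cand_R
            i += 1
        angle_step = 2.0 * math.pi / max(len(ring), 1)
        for slot, idx in enumerate(ring):
            theta = slot * angle_step
            centre = np.zeros(dims)
            centre[0] = ring_R * math.cos(theta)
            centre[1] = ring_R * math.sin(theta)
            centres.append(centre)
        outer = ring_R + ring_max

    coords = {}
    component_offsets = {}
    for rank, (res, centre) in enumerate(zip(results, centres)):
        for node, p in res.coords.items():
            coords[node] = p + centre
        component_offsets[rank] = (centre, radii[rank])
    return LayoutResult(
        coords=coords,
        dims=dims,
        component_offsets=component_offsets,
        converged=all(r.converged for r in results),
        iterations_run=sum(r.iterations_run for r in results),
    )


def write_coords_tsv(result: LayoutResult, path) -> None:
    header = ["node", "x", "y"] + (["z"] if result.dims == 3 else [])
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for node, p in result.coords.items():
            fh.write(node + "\t" + "\t".join(f"{c:.6g}" for c in p) + "\n")
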