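"""All-vs-all row correlation and thresholded correlation-graph construction.

The central capability: turn any numeric table into a weighted graph whose
nodes are the table's rows and whose edges connect rows correlated above a
threshold.  Pearson and Spearman (Pearson on within-row average ranks) are
supported.  Construction is blocked over row tiles so that the full n x n
correlation matrix is never materialised when only the thresholded graph is
needed.

Missing values are handled by pairwise-complete observation: each pair of
rows is correlated over the columns where both are observed, and pairs with
fewer than three shared observations get no edge (two points always give
|r| = 1, which would be spurious).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .graph import Graph
from .matrix import DataMatrix

PEARSON = "pearson"
SPEARMAN = "spearman"
POSITIVE_ONLY = "positive_only"
ABSOLUTE = "absolute"

MIN_SHARED_OBS = 3


@dataclass(frozen=True)
class CorrelationConfig:
    """Parameters of correlation-graph construction.

    ``r_min`` is the correlation threshold; with ``inclusive=False`` (the
    default) an edge requires r > r_min, matching the usual "r > 0.85"
    phrasing.  ``polarity`` chooses whether negative correlations can form
    edges (compared by |r|); edge weights always keep the signed r.
    """

    method: str = PEARSON
    r_min: float = 0.85
    polarity: str = POSITIVE_ONLY
    inclusive: bool = False

    def __post_init__(self) -> None:
        if self.method not in (PEARSON, SPEARMAN):
            raise ValueError(f"unknown correlation method {self.method!r}")
        if self.polarity not in (POSITIVE_ONLY, ABSOLUTE):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if not -1.0 <= self.r_min <= 1.0:
            raise ValueError(f"r_min must be in [-1, 1], got {self.r_min}")

    def passes(self, r: float) -> bool:
        value = abs(r) if self.polarity == ABSOLUTE else r
        return value >= self.r_min if self.inclusive else value > self.r_min


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Average-rank each row over its non-missing entries; NaN stays NaN."""
    out = np.full_like(values, np.nan)
    for i, row in enumerate(values):
        mask = ~np.isnan(row)
        if mask.any():
            out[i, mask] = rankdata(row[mask], method="average")
    return out


def _standardise(values: np.ndarray) -> np.ndarray:
    """Centre and L2-normalise rows so that correlation = dot product."""
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    norms[norms == 0] = 1.0  # constant row -> correlation 0 with everything
    return centred / norms


def _pairwise_complete_corr(values: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson matrix for data containing NaNs."""
    n = values.shape[0]
    out = np.eye(n)
    masks = ~np.isnan(values)
    for i in range(n):
        for j in range(i + 1, n):
            shared = masks[i] & masks[j]
            if shared.sum() < MIN_SHARED_OBS:
                out[i, j] = out[j, i] = np.nan
                continue
            x = values[i, shared]
            y = values[j, shared]
            xc = x - x.mean()
            yc = y - y.mean()
            denom = np.linalg.norm(xc) * np.linalg.norm(yc)
            out[i, j] = out[j, i] = float(xc @ yc / denom) if denom > 0 else np.nan
    return out


def _pairwise_complete_spearman(values: np.ndarray) -> np.ndarray:
    """Spearman with per-pair re-ranking over shared observations."""
    n = values.shape[0]
    out = np.eye(n)
    masks = ~np.isnan(values)
    for i in range(n):
        for j in range(i + 1, n):
            shared = masks[i] & masks[j]
            if shared.sum() < MIN_SHARED_OBS:
                out[i, j] = out[j, i] = np.nan
                continue
            x = rankdata(values[i, shared], method="average")
            y = rankdata(values[j, shared], method="average")
            xc = x - x.mean()
            yc = y - y.mean()
            denom = np.linalg.norm(xc) * np.linalg.norm(yc)
            out[i, j] = out[j, i] = float(xc @ yc / denom) if denom > 0 else np.nan
    return out


def correlation_matrix(matrix: DataMatrix, method: str = PEARSON) -> np.ndarray:
    """Symmetric row-correlation matrix with unit diagonal.

    Entries are NaN where a pair has fewer than three shared non-missing
    observations or a row is constant over the shared columns.
    """
    if method not in (PEARSON, SPEARMAN):
        raise ValueError(f"unknown correlation method {method!r}")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to correlate rows")
    values = matrix.values
    if np.isnan(values).any():
        if method == SPEARMAN:
            return _pairwise_complete_spearman(values)
        return _pairwise_complete_corr(values)
    if method == SPEARMAN:
        values = _rank_rows(values)
    z = _standardise(values)
    r = z @ z.T
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    return r


def build_correlation_graph(
    matrix: DataMatrix,
    config: CorrelationConfig | None = None,
    block_size: int = 512,
) -> Graph:
    """Thresholded correlation graph over the rows of ``matrix``.

    One node per row (node id = row id); an edge (i, j) appears iff r_ij
    passes the configured threshold, with edge weight = signed r_ij.  Row
    annotations are copied onto the nodes.  Computation proceeds in row
    tiles of ``block_size`` so memory stays O(block^2).
    """
    config = config or CorrelationConfig()
    if config.r_min == 1.0 and not config.inclusive:
        warnings.warn("r_min = 1 with strict comparison: no edge can pass")

    graph = Graph()
    graph.add_nodes(matrix.row_ids)
    for name, col in matrix.row_annotations.items():
        graph.node_attrs.set_column(name, col.kind, col.values)

    values = matrix.values
    n = values.shape[0]
    if n == 0:
        return graph
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to correlate rows")

    if np.isnan(values).any():
        # slow pairwise-complete path; no blocking needed at these sizes
        r = correlation_matrix(matrix, config.method)
        idx_i, idx_j = np.triu_indices(n, k=1)
        for i, j in zip(idx_i, idx_j):
            rij = r[i, j]
            if not np.isnan(rij) and config.passes(rij):
                graph.add_edge(matrix.row_ids[i], matrix.row_ids[j], float(rij))
        return graph

    if config.method == SPEARMAN:
        values = _rank_rows(values)
    z = _standardise(values)

    ids = matrix.row_ids
    for bi in range(0, n, block_size):
        zi = z[bi : bi + block_size]
        for bj in range(bi, n, block_size):
            tile = zi @ z[bj : bj + block_size].T
            np.clip(tile, -1.0, 1.0, out=tile)
            if config.polarity == ABSOLUTE:
                mask = (
                    np.abs(tile) >= config.r_min
                    if config.inclusive
                    else np.abs(tile) > config.r_min
                )
            else:
                mask = tile >= config.r_min if config.inclusive else tile > config.r_min
            if bi == bj:
                mask = np.triu(mask, k=1)
            for ii, jj in zip(*np.nonzero(mask)):
                graph.add_edge(ids[bi + ii], ids[bj + jj], float(tile[ii, jj]))
    return graph
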