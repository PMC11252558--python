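"""Sparsity-thresholded weighted-graph efficiency metrics.

The connectivity matrix is binarized in density, not in value: each subject
keeps the same fixed ratio of strongest edges (the sparsity), realized by a
subject-specific cutoff. Efficiency metrics are computed on the surviving
weighted graph with edge length 1/weight (stronger coupling = shorter
distance), so disconnected node pairs contribute 0 through 1/inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

DEFAULT_SPARSITY = 0.2


@dataclass
class ThresholdedNetwork:
    """Weighted network after sparsity thresholding."""

    weights: np.ndarray        # symmetric, non-negative, zero diagonal
    sparsity: float
    threshold: float           # realized per-subject cutoff (smallest kept weight)
    channel_labels: list[str] | None = None


@dataclass
class NetworkMetrics:
    """Shortest-path distances and efficiency summaries."""

    distances: np.ndarray      # (N, N), np.inf where unreachable
    global_efficiency: float
    nodal_efficiency: np.ndarray  # (N,)
    sparsity: float
    channel_labels: list[str] | None = None


def apply_sparsity_threshold(
    matrix: np.ndarray,
    sparsity: float = DEFAULT_SPARSITY,
    channel_labels: list[str] | None = None,
) -> ThresholdedNetwork:
    """Keep the ``round(sparsity * N(N-1)/2)`` strongest edges, zero the rest.

    The edge count uses round-half-even. Ties at the cutoff are broken by
    (row, col) lexicographic order among the tied edges, so the result is
    deterministic.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n):
        raise ValueError("matrix must be square")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("matrix must be symmetric")
    if (matrix < 0).any():
        raise ValueError("matrix must be non-negative")
    if not (0 < sparsity <= 1):
        raise ValueError("sparsity must lie in (0, 1]")

    iu, ju = np.triu_indices(n, k=1)
    weights = matrix[iu, ju]
    n_possible = n * (n - 1) // 2
    n_keep = int(round(sparsity * n_possible))  # round-half-even
    # sort by (-weight, row, col): strongest first, lexicographic tie-break
    order = np.lexsort((ju, iu, -weights))
    kept = order[:n_keep]
    out = np.zeros_like(matrix)
    out[iu[kept], ju[kept]] = weights[kept]
    out[ju[kept], iu[kept]] = weights[kept]
    threshold = float(weights[kept].min()) if n_keep else float("inf")
    return ThresholdedNetwork(
        weights=out, sparsity=sparsity, threshold=threshold,
        channel_labels=channel_labels,
    )


def shortest_distances(net: ThresholdedNetwork) -> np.ndarray:
    """All-pairs weighted shortest-path distances with edge length 1/weight."""
    w = net.weights
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    d = dijkstra(csr_matrix(lengths), directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def global_efficiency(d: np.ndarray) -> float:
    """Mean inverse distance over the N(N-1)/2 unordered node pairs.

    Unreachable pairs contribute 0 (1/inf), keeping the value finite.
    """
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d[iu, ju]), 0.0, 1.0 / d[iu, ju])
    return float(inv.mean())


def nodal_efficiency(d: np.ndarray, node: int | None = None) -> np.ndarray | float:
    """Per-node mean inverse distance to every other node.

    ``(1/(N-1)) * sum_{j != i} 1/d_ij``. With ``node`` given, returns that
    node's scalar; otherwise the full vector.
    """
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d) | (d == 0), 0.0, 1.0 / d)
    np.fill_diagonal(inv, 0.0)
    eff = inv.sum(axis=1) / (n - 1)
    if node is not None:
        return float(eff[node])
    return eff


def network_metrics(
    matrix: np.ndarray,
    sparsity: float = DEFAULT_SPARSITY,
    channel_labels: list[str] | None = None,
) -> NetworkMetrics:
    """Threshold a connectivity matrix and compute efficiency metrics."""
    net = apply_sparsity_threshold(matrix, sparsity, channel_labels)
    d = shortest_distances(net)
    return NetworkMetrics(
        distances=d,
        global_efficiency=global_efficiency(d),
        nodal_efficiency=np.asarray(nodal_efficiency(d)),
        sparsity=sparsity,
        channel_labels=channel_labels,
    )


def sparsity_sweep(
    matrix: np.ndarray,
    sparsities=(0.1, 0.2, 0.3, 0.4, 0.5),
    channel_labels: list[str] | None = None,
) -> dict[float, NetworkMetrics]:
    """Efficiency metrics over a grid of sparsity levels."""
    return {s: network_metrics(matrix, s, channel_labels) for s in sparsities}
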