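"""Weighted graph-theoretic measures for hemispheric FA networks.

Edge weights are fractional anisotropy values in [0, 1]; topological
distance between connected regions is the reciprocal weight, so a
strong (high-FA) connection is a short path.  With weights bounded by
1 every finite shortest-path distance is at least 1, which keeps all
efficiency measures in [0, 1].

Measures:

* ``Lp`` — characteristic path length: mean shortest-path distance over
  ordered node pairs, restricted to connected (finite-distance) pairs;
  the number of connected pairs is tracked so fragmentation is visible.
* ``Eg`` — global efficiency: mean of reciprocal distances over all
  ordered pairs, with 1/inf = 0 for disconnected pairs.
* ``Enodal(i)`` — nodal efficiency: mean reciprocal distance from node
  i to every other node.  The node-wise mean of Enodal equals Eg
  identically (both average 1/d over the same ordered pairs).
* ``Cp`` — weighted clustering coefficient, Onnela geometric-mean form
  with weights normalised by the network maximum; nodes with degree
  below 2 score 0 and stay in the average.
* ``Eloc`` — local efficiency: mean over nodes of the global efficiency
  of the neighbourhood subgraph (neighbours of i with their original
  weights, i excluded); degree < 2 contributes 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import dijkstra

from .construction import HemisphericNetwork

__all__ = [
    "DistanceMatrix",
    "MetricSet",
    "weight_to_length",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "nodal_efficiency",
    "nodal_efficiency_vector",
    "clustering_coefficient",
    "local_efficiency",
    "compute_metric_set",
    "GLOBAL_METRIC_NAMES",
]

logger = logging.getLogger(__name__)

DistanceMatrix = np.ndarray  # shortest-path lengths, np.inf for unreachable

GLOBAL_METRIC_NAMES = ("Cp", "Lp", "Eg", "Eloc")


@dataclass
class MetricSet:
    """Global measures plus the nodal-efficiency vector for one network."""

    cp: float
    lp: float
    eg: float
    eloc: float
    enodal: np.ndarray
    n_connected_pairs: int

    def as_dict(self) -> dict[str, float]:
        return {"Cp": self.cp, "Lp": self.lp, "Eg": self.eg, "Eloc": self.eloc}


def weight_to_length(adjacency: np.ndarray) -> np.ndarray:
    """Map FA weights to path lengths: length = 1/weight, no edge = inf."""
    w = np.asarray(adjacency, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative edge weight")
    with np.errstate(divide="ignore"):
        length = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(length, 0.0)
    return length


def shortest_paths(length: np.ndarray) -> DistanceMatrix:
    """All-pairs shortest-path distances on a nonnegative length matrix."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("negative length")
    # dijkstra treats 0 as "no edge" in the graph, so mask the diagonal
    # and rely on directed=False for symmetry.
    return dijkstra(length, directed=False)


def characteristic_path_length(distances: DistanceMatrix) -> float:
    """Mean shortest-path distance over connected ordered pairs.

    Unreachable pairs are excluded (their count is logged); an entirely
    disconnected network raises, since the mean is undefined.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    n_excluded = int(off.sum() - finite.sum())
    if finite.sum() == 0:
        raise ValueError("empty network: no finite-distance node pair")
    if n_excluded:
        logger.debug("Lp computed over %d pairs; %d disconnected pairs excluded",
                     int(finite.sum()), n_excluded)
    return float(d[finite].mean())


def global_efficiency(distances: DistanceMatrix) -> float:
    """Mean reciprocal distance over all ordered pairs (1/inf = 0)."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def nodal_efficiency_vector(distances: DistanceMatrix) -> np.ndarray:
    """Per-node efficiency: mean reciprocal distance to all other nodes."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 2:
        return np.zeros(n)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return inv.sum(axis=1) / (n - 1)


def nodal_efficiency(distances: DistanceMatrix, node: int) -> float:
    n = np.asarray(distances).shape[0]
    if not 0 <= node < n:
        raise IndexError(f"node index {node} out of range for {n} nodes")
    return float(nodal_efficiency_vector(distances)[node])


def clustering_coefficient(adjacency: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted clustering (Onnela geometric-mean form).

    Weights are normalised by the network maximum; the per-node
    coefficient is the sum of cube-rooted triangle weights around the
    node divided by k(k-1).  Returns (network mean, per-node vector).
    """
    w = np.asarray(adjacency, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0, np.zeros(n)
    w_hat = np.cbrt(w / wmax)
    triangles = np.diag(w_hat @ w_hat @ w_hat)  # 2 * sum of triangle weights
    degree = (w > 0).sum(axis=1)
    denom = degree * (degree - 1)
    c = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return float(c.mean()), c


def local_efficiency(adjacency: np.ndarray) -> float:
    """Mean global efficiency of each node's neighbourhood subgraph.

    Neighbourhoods keep the original FA weights; nodes with fewer than
    two neighbours contribute 0.
    """
    w = np.asarray(adjacency, dtype=float)
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        total += global_efficiency(shortest_paths(weight_to_length(sub)))
    return total / n if n else 0.0


def compute_metric_set(network: HemisphericNetwork) -> MetricSet:
    """All measures for one hemispheric network from a single distance pass."""
    w = network.adjacency
    d = shortest_paths(weight_to_length(w))
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    n_connected = int((off & np.isfinite(d)).sum())
    cp, _ = clustering_coefficient(w)
    return MetricSet(
        cp=cp,
        lp=characteristic_path_length(d),
        eg=global_efficiency(d),
        eloc=local_efficiency(w),
        enodal=nodal_efficiency_vector(d),
        n_connected_pairs=n_connected,
    )
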