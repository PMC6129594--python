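"""Independent brute-force oracles for graph measures.

Deliberately naive: exhaustive simple-path enumeration for shortest
paths, direct evaluation of the clustering formula, and the local-
efficiency definition spelled out, so they share no code path with the
package implementations they check.
"""

import itertools

import numpy as np


def brute_shortest_paths(length: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by enumerating every simple path.

    Only feasible for very small graphs (<= ~7 nodes).
    """
    n = length.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    nodes = range(n)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            best = np.inf
            inner = [v for v in nodes if v not in (s, t)]
            for r in range(len(inner) + 1):
                for mid in itertools.permutations(inner, r):
                    path = (s, *mid, t)
                    cost = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if not np.isfinite(length[a, b]):
                            ok = False
                            break
                        cost += length[a, b]
                    if ok and cost < best:
                        best = cost
            d[s, t] = best
    return d


def brute_clustering(w: np.ndarray) -> tuple[float, np.ndarray]:
    """Onnela geometric-mean weighted clustering, written out directly."""
    n = w.shape[0]
    wmax = w.max()
    c = np.zeros(n)
    if wmax == 0:
        return 0.0, c
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for j in nbrs:
            for h in nbrs:
                if j == h:
                    continue
                if w[j, h] > 0:
                    s += ((w[i, j] / wmax) * (w[i, h] / wmax)
                          * (w[j, h] / wmax)) ** (1.0 / 3.0)
        c[i] = s / (k * (k - 1))
    return float(c.mean()), c


def brute_global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        length = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(length, 0.0)
    d = brute_shortest_paths(length)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def brute_local_efficiency(w: np.ndarray) -> float:
    """Mean over nodes of the neighbourhood subgraph's global efficiency."""
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        total += brute_global_efficiency(sub)
    return total / n if n else 0.0
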