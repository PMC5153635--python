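"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately naive: simple-path enumeration for
shortest paths and betweenness, explicit triangle loops for clustering,
plain sums for strength/degree.  Only feasible for tiny graphs (K <= 7),
which is exactly the regime the oracle-equivalence tests use.
"""

from __future__ import annotations

import itertools

import numpy as np

TOL = 1e-9


def _all_simple_paths(w: np.ndarray, s: int, t: int):
    """Yield every simple path s -> t as a node tuple."""
    k = w.shape[0]

    def extend(path):
        last = path[-1]
        if last == t:
            yield tuple(path)
            return
        for nxt in range(k):
            if w[last, nxt] > 0 and nxt not in path:
                yield from extend(path + [nxt])

    yield from extend([s])


def shortest_paths_brute(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths on 1/w edge lengths."""
    k = w.shape[0]
    d = np.full((k, k), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(k):
        for t in range(k):
            if s == t:
                continue
            best = np.inf
            for path in _all_simple_paths(w, s, t):
                length = sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))
                best = min(best, length)
            d[s, t] = best
    return d


def path_length_brute(w: np.ndarray) -> float:
    """Mean finite off-diagonal shortest-path length."""
    d = shortest_paths_brute(w)
    k = w.shape[0]
    off = ~np.eye(k, dtype=bool)
    finite = np.isfinite(d) & off
    return float(d[finite].mean())


def betweenness_brute(w: np.ndarray) -> np.ndarray:
    """Normalized betweenness by exhaustive shortest-path enumeration."""
    k = w.shape[0]
    bt = np.zeros(k)
    for s, t in itertools.combinations(range(k), 2):
        paths = []
        best = np.inf
        for path in _all_simple_paths(w, s, t):
            length = sum(1.0 / w[a, b] for a, b in zip(path, path[1:]))
            if length < best - TOL:
                best = length
                paths = [path]
            elif abs(length - best) <= TOL:
                paths.append(path)
        if not paths or not np.isfinite(best):
            continue
        for v in range(k):
            if v in (s, t):
                continue
            via = sum(1 for p in paths if v in p)
            bt[v] += via / len(paths)
    return bt * 2.0 / ((k - 1) * (k - 2))


def clustering_brute(w: np.ndarray) -> float:
    """Weighted clustering (geometric-mean triangles), averaged over nodes."""
    k = w.shape[0]
    wn = w / w.max()
    c = np.zeros(k)
    for i in range(k):
        deg = int(np.sum(w[i] > 0))
        if deg < 2:
            continue
        tri = 0.0
        for j in range(k):
            for h in range(k):
                if j == i or h == i or j == h:
                    continue
                tri += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        c[i] = tri / (deg * (deg - 1))
    return float(c.mean())


def strength_brute(w: np.ndarray) -> np.ndarray:
    return np.array([sum(w[i, j] for j in range(w.shape[0])) for i in range(w.shape[0])])


def degree_brute(w: np.ndarray) -> np.ndarray:
    return np.array([sum(1 for j in range(w.shape[0]) if w[i, j] > 0) for i in range(w.shape[0])])


def random_small_graph(rng: np.random.Generator, k: int | None = None) -> np.ndarray:
    """Random connected-ish weighted graph with K <= 7 and distinct weights."""
    k = k or int(rng.integers(3, 8))
    w = np.zeros((k, k))
    for i, j in itertools.combinations(range(k), 2):
        if rng.random() < 0.6:
            w[i, j] = w[j, i] = rng.uniform(0.2, 1.0)
    if not np.any(w):
        w[0, 1] = w[1, 0] = rng.uniform(0.2, 1.0)
    return w
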