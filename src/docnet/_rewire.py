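"""Degree-preserving double-edge-swap kernel.

The loop is compiled with numba when available; the pure-python fallback
is the same algorithm and produces identical output for identical random
draws (all randomness is pre-drawn outside the kernel).
"""

from __future__ import annotations

import numpy as np


def _swap_kernel(u, v, adj, pick1, pick2, flip):
    accepted = 0
    for t in range(pick1.shape[0]):
        e1 = pick1[t]
        e2 = pick2[t]
        if e1 == e2:
            continue
        a = u[e1]
        b = v[e1]
        c = u[e2]
        d = v[e2]
        if flip[t] == 1:
            c, d = d, c
        # propose (a,b),(c,d) -> (a,d),(c,b)
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        u[e1] = a
        v[e1] = d
        u[e2] = c
        v[e2] = b
        accepted += 1
    return accepted


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _swap_kernel_jit = njit(cache=True)(_swap_kernel)
except Exception:  # pragma: no cover
    _swap_kernel_jit = _swap_kernel


def double_edge_swap(
    u: np.ndarray,
    v: np.ndarray,
    n_nodes: int,
    n_attempts: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Rewire an edge list in place-preserving copies; returns (u, v, accepted)."""
    u = u.astype(np.int64).copy()
    v = v.astype(np.int64).copy()
    n_edges = u.size
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    adj[u, v] = True
    adj[v, u] = True
    picks = rng.integers(0, n_edges, size=(2, n_attempts))
    flip = rng.integers(0, 2, size=n_attempts)
    accepted = _swap_kernel_jit(u, v, adj, picks[0], picks[1], flip)
    return u, v, int(accepted)
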