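"""Topological metrics of thresholded weighted graphs.

Nodal metrics are connectivity strength (row sum of weights), degree and
weighted shortest-path betweenness; global metrics are the weighted
clustering coefficient (geometric-mean triangle form) and characteristic
path length.  Shortest paths use edge lengths 1/w, the standard mapping
for correlation-weighted graphs.  All metrics are normalized against
degree-matched rewired null graphs, and density profiles are summarized
by the trapezoidal area under the curve over the admissible densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from ._rewire import double_edge_swap
from ._seeds import derive_seed
from .errors import RewiringStallWarning, UndefinedMetricError, UndefinedSigmaError
from .graphs import DensityGrid, ThresholdedGraph, threshold_by_density
from .synthetic import Parcellation

METRICS = ("strength", "betweenness", "degree")


@dataclass
class NodalMetrics:
    """Per-node strength, degree and normalized betweenness at one density."""

    strength: np.ndarray
    degree: np.ndarray
    betweenness: np.ndarray
    density: float | None = None


def nodal_metrics(g: ThresholdedGraph, with_betweenness: bool = True) -> NodalMetrics:
    """Strength, degree and (optionally) weighted betweenness of a graph.

    Betweenness is computed on edge lengths 1/w and normalized by
    2/((K-1)(K-2)) so that a node lying on every geodesic scores 1.
    """
    w = g.weights
    k = w.shape[0]
    if k < 3:
        raise UndefinedMetricError(f"betweenness undefined for K={k} < 3")
    strength = w.sum(axis=1)
    degree = (w > 0).sum(axis=1)
    if with_betweenness:
        bt = _betweenness(w) * (2.0 / ((k - 1) * (k - 2)))
    else:
        bt = np.full(k, np.nan)
    return NodalMetrics(
        strength=strength, degree=degree, betweenness=bt, density=g.density
    )


def _betweenness(w: np.ndarray) -> np.ndarray:
    k = w.shape[0]
    i, j = np.nonzero(np.triu(w, 1))
    return _betweenness_edges(k, i, j, w[i, j])


def _betweenness_edges(k: int, u: np.ndarray, v: np.ndarray, w: np.ndarray) -> np.ndarray:
    import igraph as ig

    if u.size == 0:
        return np.zeros(k)
    graph = ig.Graph(n=k, edges=list(zip(u.tolist(), v.tolist())))
    lengths = (1.0 / w).tolist()
    return np.asarray(graph.betweenness(weights=lengths), dtype=float)


def _edge_nodal_metrics(
    k: int,
    u: np.ndarray,
    v: np.ndarray,
    w: np.ndarray,
    metrics: tuple[str, ...],
) -> dict[str, np.ndarray]:
    """Nodal metrics straight from an edge list (no dense matrix)."""
    out: dict[str, np.ndarray] = {}
    if "strength" in metrics:
        s = np.zeros(k)
        np.add.at(s, u, w)
        np.add.at(s, v, w)
        out["strength"] = s
    if "degree" in metrics:
        d = np.zeros(k)
        np.add.at(d, u, 1.0)
        np.add.at(d, v, 1.0)
        out["degree"] = d
    if "betweenness" in metrics:
        out["betweenness"] = _betweenness_edges(k, u, v, w) * (
            2.0 / ((k - 1) * (k - 2))
        )
    return out


def network_mean(values: np.ndarray, parc: Parcellation, network: str) -> float:
    """Arithmetic mean of a nodal quantity over one network's nodes."""
    idx = parc.nodes_of(network)  # raises KeyError for unknown networks
    return float(np.mean(np.asarray(values, dtype=float)[idx]))


def global_metrics(g: ThresholdedGraph) -> tuple[float, float]:
    """(clustering, characteristic path length) of a weighted graph.

    Clustering is the geometric-mean triangle coefficient on weights
    scaled by the maximum weight, averaged over all nodes (nodes with
    degree < 2 contribute 0).  Path length is the mean finite
    shortest-path length on 1/w edge lengths; disconnected pairs are
    excluded.
    """
    w = g.weights
    k = w.shape[0]
    if k < 3:
        raise UndefinedMetricError(f"global metrics undefined for K={k} < 3")
    if g.n_edges == 0:
        raise UndefinedMetricError("graph has no edges")
    wn = w / w.max()
    cr = np.cbrt(wn)
    tri = np.einsum("ij,jk,ki->i", cr, cr, cr)
    deg = (w > 0).sum(axis=1)
    denom = deg * (deg - 1)
    c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    clustering = float(c.mean())

    lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    off = ~np.eye(k, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        raise UndefinedMetricError("no connected node pairs")
    path_length = float(d[finite].mean())
    return clustering, path_length


def _null_edge_stream(
    g: ThresholdedGraph,
    n_nulls: int,
    seed: int,
    swaps_per_edge: int = 10,
):
    """Yield (u, v, shuffled weights) for each rewired null."""
    i, j, w = g.edge_list()
    if i.size == 0:
        raise UndefinedMetricError("cannot rewire a graph with no edges")
    k = g.n_nodes
    for b in range(n_nulls):
        rng = np.random.default_rng(derive_seed(seed, "rewire", b))
        u, v, accepted = double_edge_swap(
            i, j, k, n_attempts=swaps_per_edge * i.size, rng=rng
        )
        if accepted == 0 and i.size > 1:
            warnings.warn(
                "rewiring accepted no swaps (graph too sparse or rigid)",
                RewiringStallWarning,
            )
        yield u, v, w[rng.permutation(w.size)]


def rewire_null(
    g: ThresholdedGraph,
    n_nulls: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> list[ThresholdedGraph]:
    """Degree-matched null graphs via Maslov-Sneppen double-edge swaps.

    Each null rewires the binary topology with ``swaps_per_edge * E``
    swap attempts and then reassigns the original multiset of weights to
    the rewired edges in random order.  Degree sequence, edge count and
    weight multiset are preserved exactly.
    """
    k = g.n_nodes
    nulls = []
    for u, v, wsh in _null_edge_stream(g, n_nulls, seed, swaps_per_edge):
        wm = np.zeros((k, k))
        wm[u, v] = wsh
        wm = wm + wm.T
        nulls.append(ThresholdedGraph(weights=wm, density=g.density))
    return nulls


def normalize(real, nulls) -> np.ndarray | float:
    """Elementwise real / mean(nulls).

    Zero null mean with zero real value yields 1; zero null mean with a
    nonzero real value yields NaN, a sentinel later excluded from AUC
    summaries.
    """
    if len(nulls) == 0:
        raise ValueError("need at least one null value")
    real_arr = np.asarray(real, dtype=float)
    null_arr = np.asarray(nulls, dtype=float)
    if null_arr.shape[1:] != real_arr.shape:
        raise ValueError(
            f"null shape {null_arr.shape[1:]} does not match real {real_arr.shape}"
        )
    m = null_arr.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            m != 0, real_arr / np.where(m != 0, m, 1.0),
            np.where(real_arr == 0, 1.0, np.nan),
        )
    if np.isscalar(real) or real_arr.ndim == 0:
        return float(out)
    return out


def small_worldness(
    g: ThresholdedGraph, nulls: list[ThresholdedGraph]
) -> float:
    """sigma = (C / <C_null>) / (L / <L_null>)."""
    c, el = global_metrics(g)
    stats = [global_metrics(n) for n in nulls]
    c_null = float(np.mean([s[0] for s in stats]))
    l_null = float(np.mean([s[1] for s in stats]))
    if c_null == 0 or l_null == 0 or el == 0:
        raise UndefinedSigmaError("zero null means; sigma undefined")
    return (c / c_null) / (el / l_null)


def auc_over_densities(values, densities) -> float:
    """Trapezoidal integral of a metric profile over density (fractions).

    NaN entries (non-finite normalization sentinels) are dropped; at
    least two finite points are required.  The result is invariant to
    reversing both lists.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(densities, dtype=float)
    if x.size != y.size:
        raise ValueError("values and densities must be aligned")
    if x.size < 2:
        raise ValueError("AUC needs at least two densities")
    keep = np.isfinite(y)
    if keep.sum() < 2:
        raise ValueError("AUC needs at least two finite values")
    x, y = x[keep], y[keep]
    order = np.argsort(x)
    return float(np.trapezoid(y[order], x[order]))


@dataclass
class TopologyProfile:
    """Raw and null-normalized metric profiles for one subject.

    ``raw[m]`` and ``normalized[m]`` are (n_densities, K) arrays for each
    metric m; ``gamma``/``lam``/``sigma`` are the normalized clustering,
    normalized path length and their ratio per density; ``nodal_auc`` and
    ``network_auc`` summarize the selected (admissible) densities.
    """

    subject_id: str | None
    group: str | None
    densities: np.ndarray
    raw: dict[str, np.ndarray]
    normalized: dict[str, np.ndarray]
    gamma: np.ndarray | None = None
    lam: np.ndarray | None = None
    sigma: np.ndarray | None = None
    nodal_auc: dict[str, np.ndarray] = field(default_factory=dict)
    network_auc: dict[str, dict[str, float]] = field(default_factory=dict)

    def feature_values(self, metric: str, normalized: bool = True) -> np.ndarray:
        src = self.nodal_auc if normalized else self._raw_auc_cache()
        return src[metric]

    _raw_auc: dict[str, np.ndarray] | None = None

    def _raw_auc_cache(self) -> dict[str, np.ndarray]:
        if self._raw_auc is None:
            dens = self.densities
            self._raw_auc = {
                m: np.array(
                    [auc_over_densities(self.raw[m][:, i], dens)
                     for i in range(self.raw[m].shape[1])]
                )
                for m in self.raw
            }
        return self._raw_auc


def subject_topology(
    c,
    grid: DensityGrid,
    parc: Parcellation | None = None,
    n_nulls: int = 100,
    seed: int = 0,
    metrics: tuple[str, ...] = METRICS,
    normalized: bool = True,
    normalize_metrics: tuple[str, ...] = ("strength", "betweenness"),
    with_small_world: bool = False,
    graphs_by_density: list[ThresholdedGraph] | None = None,
) -> TopologyProfile:
    """Metric profiles of one subject across the admissible densities.

    For each admissible density the thresholded graph and one shared
    ensemble of ``n_nulls`` rewired nulls are built; raw metrics, their
    null-normalized versions and (optionally) gamma/lambda/sigma are
    computed from the same ensemble, then AUC-summarized over density.

    ``normalize_metrics`` selects which metrics are divided by their
    null means.  Degree is never normalized (degree-matched nulls make
    that ratio identically 1); betweenness is scale-invariant already,
    so dropping it from the set trades its null ensemble for speed.
    """
    densities = grid.admissible_densities
    if densities.size < 2:
        raise ValueError("need at least two admissible densities")
    k = c.z.shape[0]
    with_bt = "betweenness" in metrics
    raw: dict[str, list[np.ndarray]] = {m: [] for m in metrics}
    norm: dict[str, list[np.ndarray]] = {m: [] for m in metrics}
    gammas, lams, sigmas = [], [], []
    if graphs_by_density is not None and len(graphs_by_density) != densities.size:
        raise ValueError("graphs_by_density does not match the admissible grid")
    for di, d in enumerate(densities):
        g = (
            graphs_by_density[di]
            if graphs_by_density is not None
            else threshold_by_density(c, float(d))
        )
        nm = nodal_metrics(g, with_betweenness=with_bt)
        vals = {m: getattr(nm, m).astype(float) for m in metrics}
        for m in metrics:
            raw[m].append(vals[m])
        need_nulls = (normalized or with_small_world) and n_nulls > 0
        # degree-preserving nulls make normalized degree identically 1;
        # degree stays raw to remain informative
        null_metrics = tuple(
            m for m in metrics if m != "degree" and m in normalize_metrics
        )
        if need_nulls:
            null_vals: dict[str, list[np.ndarray]] = {m: [] for m in null_metrics}
            null_globals = []
            for u, v, wsh in _null_edge_stream(
                g, n_nulls, derive_seed(seed, "nulls", di)
            ):
                if normalized and null_metrics:
                    em = _edge_nodal_metrics(k, u, v, wsh, null_metrics)
                    for m in null_metrics:
                        null_vals[m].append(em[m])
                if with_small_world:
                    wm = np.zeros((k, k))
                    wm[u, v] = wsh
                    null_globals.append(
                        global_metrics(ThresholdedGraph(wm + wm.T, g.density))
                    )
        if normalized and need_nulls:
            for m in metrics:
                if m in null_metrics:
                    norm[m].append(np.asarray(normalize(vals[m], null_vals[m])))
                else:
                    norm[m].append(vals[m])
        else:
            for m in metrics:
                norm[m].append(vals[m])
        if with_small_world and need_nulls:
            cg, lg = global_metrics(g)
            gamma = cg / float(np.mean([s[0] for s in null_globals]))
            lam = lg / float(np.mean([s[1] for s in null_globals]))
            gammas.append(gamma)
            lams.append(lam)
            sigmas.append(gamma / lam)

    raw_arr = {m: np.vstack(raw[m]) for m in metrics}
    norm_arr = {m: np.vstack(norm[m]) for m in metrics}
    nodal_auc = {
        m: np.array(
            [auc_over_densities(norm_arr[m][:, i], densities) for i in range(k)]
        )
        for m in metrics
    }
    network_auc: dict[str, dict[str, float]] = {}
    if parc is not None:
        for m in metrics:
            network_auc[m] = {
                net: network_mean(nodal_auc[m], parc, net) for net in parc.networks
            }
    return TopologyProfile(
        subject_id=getattr(c, "subject_id", None),
        group=getattr(c, "group", None),
        densities=densities,
        raw=raw_arr,
        normalized=norm_arr,
        gamma=np.asarray(gammas) if gammas else None,
        lam=np.asarray(lams) if lams else None,
        sigma=np.asarray(sigmas) if sigmas else None,
        nodal_auc=nodal_auc,
        network_auc=network_auc,
    )
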