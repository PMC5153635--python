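"""Proportional density thresholding of connectivity matrices.

A weighted graph is built at each connection density of an inclusive
grid (defaults 2.5-32.5 % in steps of 2 %): the upper-triangle |z|
values are sorted from high to low and the top ``round(d*K*(K-1)/2)``
entries keep their |z| as edge weight, everything else is zero.  A
density is admissible when fewer than 10 % of nodes are unconnected and
the graph's small-worldness exceeds 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix
from .errors import (
    EmptyAdmissibleWarning,
    EmptyGraphWarning,
    InvalidDensityError,
    InvalidStepError,
)


@dataclass
class ThresholdedGraph:
    """Weighted undirected graph retained at one connection density."""

    weights: np.ndarray
    density: float

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def degree(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=1)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(i, j, w) arrays over the upper triangle, i < j."""
        i, j = np.nonzero(np.triu(self.weights, 1))
        return i, j, self.weights[i, j]


@dataclass
class DensityGrid:
    """Ordered density fractions with per-density admissibility flags."""

    densities: np.ndarray
    admissible: np.ndarray

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.admissible = np.asarray(self.admissible, dtype=bool)
        if np.any(np.diff(self.densities) <= 0):
            raise InvalidStepError("densities must be strictly increasing")

    @property
    def admissible_densities(self) -> np.ndarray:
        return self.densities[self.admissible]

    def __len__(self) -> int:
        return int(self.densities.size)


def density_grid(
    start: float = 0.025, stop: float = 0.325, step: float = 0.02
) -> DensityGrid:
    """Inclusive arithmetic density sequence, all marked admissible."""
    if step <= 0:
        raise InvalidStepError(f"step must be positive, got {step}")
    if not (0 < start <= stop <= 1):
        raise InvalidDensityError(f"invalid range [{start}, {stop}]")
    n = int(np.floor((stop - start) / step + 1e-9)) + 1
    densities = start + step * np.arange(n)
    return DensityGrid(densities=densities, admissible=np.ones(n, dtype=bool))


def edge_count(n_nodes: int, density: float) -> int:
    """Edges retained at a density: round-half-away-from-zero."""
    return int(np.floor(density * n_nodes * (n_nodes - 1) / 2.0 + 0.5))


def threshold_by_density(c: ConnectivityMatrix, density: float) -> ThresholdedGraph:
    """Keep the highest-|z| edges at the requested connection density.

    Ties in |z| are broken by ascending (i, j) lexicographic order, which
    makes the retained edge sets nested across densities.
    """
    if not (0 < density <= 1):
        raise InvalidDensityError(f"density must be in (0, 1], got {density}")
    z = c.z
    k = z.shape[0]
    i, j = np.triu_indices(k, 1)
    a = np.abs(z[i, j])
    m = edge_count(k, density)
    w = np.zeros_like(z)
    if m == 0:
        warnings.warn(
            f"density {density} retains no edges for K={k}", EmptyGraphWarning
        )
        return ThresholdedGraph(weights=w, density=density)
    # lexsort: last key is primary -> sort by -|z|, then i, then j
    order = np.lexsort((j, i, -a))[:m]
    w[i[order], j[order]] = a[order]
    w = w + w.T
    return ThresholdedGraph(weights=w, density=density)


def fraction_unconnected(g: ThresholdedGraph) -> float:
    """Share of nodes with degree zero."""
    return float(np.mean(g.degree() == 0))


def select_density_range(
    c: ConnectivityMatrix,
    grid: DensityGrid,
    null_count: int = 100,
    seed: int = 0,
    max_unconnected: float = 0.10,
    sigma_min: float = 1.5,
) -> DensityGrid:
    """Mark densities admissible by the two graph-quality criteria.

    A density is admissible iff the thresholded graph leaves fewer than
    ``max_unconnected`` of nodes unconnected and its small-worldness
    against ``null_count`` degree-matched rewired nulls exceeds
    ``sigma_min``.
    """
    from . import topology  # deferred: topology imports graphs

    if len(grid) == 0:
        raise InvalidStepError("empty density grid")
    flags = np.zeros(len(grid), dtype=bool)
    for idx, d in enumerate(grid.densities):
        g = threshold_by_density(c, float(d))
        if g.n_edges == 0 or fraction_unconnected(g) >= max_unconnected:
            continue
        nulls = topology.rewire_null(g, n_nulls=null_count, seed=seed + idx)
        try:
            sigma = topology.small_worldness(g, nulls)
        except Exception:
            continue
        flags[idx] = sigma > sigma_min
    if not flags.any():
        warnings.warn(
            "no density satisfied the admissibility criteria", EmptyAdmissibleWarning
        )
    return DensityGrid(densities=grid.densities.copy(), admissible=flags)


def intersect_admissible(grids: list[DensityGrid]) -> DensityGrid:
    """Cohort-level admissible range: densities admissible for every subject."""
    if not grids:
        raise ValueError("no grids to intersect")
    base = grids[0].densities
    flags = np.ones_like(grids[0].admissible)
    for g in grids:
        if not np.allclose(g.densities, base):
            raise ValueError("grids are not aligned")
        flags = flags & g.admissible
    return DensityGrid(densities=base.copy(), admissible=flags)
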