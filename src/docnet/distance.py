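"""Distance-binned connectivity profiles.

Each node of a target network is paired with every other node of the
whole-brain graph; pairs are binned by the Euclidean distance between
node centres into 18 intervals of 10 mm covering 0-180 mm (half-open
[low, high), last bin closed), and the mean edge weight per bin is the
distance profile.  75 mm is the conventional short/long-range cut.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import f_oneway, tukey_hsd

from .errors import BinSkippedWarning, OutOfRangeDistanceError
from .graphs import ThresholdedGraph
from .synthetic import Parcellation

BIN_EDGES_MM = np.arange(0.0, 190.0, 10.0)  # 19 edges -> 18 bins
N_BINS = 18
LONG_RANGE_MM = 75.0


@dataclass
class DistanceProfile:
    """Mean edge weight per 10 mm distance bin for one (subject, network).

    ``mean_strength`` is NaN for empty bins (flagged missing, not
    zero-filled); ``counts`` holds the number of node pairs per bin.
    """

    network: str
    bin_edges: np.ndarray
    mean_strength: np.ndarray
    counts: np.ndarray
    subject_id: str | None = None
    group: str | None = None

    @property
    def bin_midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


def distance_matrix(parc: Parcellation) -> np.ndarray:
    """Symmetric Euclidean distance matrix (mm) between node centres."""
    if not np.all(np.isfinite(parc.coords)):
        raise ValueError("non-finite coordinates")
    return cdist(parc.coords, parc.coords)


def _bin_index(d: np.ndarray) -> np.ndarray:
    # [low, high) bins of 10 mm; the last bin [170, 180] is closed above.
    idx = np.floor(d / 10.0).astype(int)
    idx[np.isclose(d, 180.0)] = N_BINS - 1
    return idx


def binned_strength(
    g: ThresholdedGraph | np.ndarray,
    dist: np.ndarray,
    parc: Parcellation,
    network: str,
    subject_id: str | None = None,
    group: str | None = None,
) -> DistanceProfile:
    """Distance profile of one network's connectivity to the whole brain.

    Pairs run from every node of ``network`` to every other node of the
    graph (network-internal and -external alike); each ordered pair
    contributes its edge weight (zero if the edge did not survive
    thresholding) to the mean of its distance bin.
    """
    w = g.weights if isinstance(g, ThresholdedGraph) else np.asarray(g, dtype=float)
    k = w.shape[0]
    if dist.shape != (k, k) or parc.n_nodes != k:
        raise ValueError("graph, distance matrix and parcellation shapes differ")
    rows = parc.nodes_of(network)
    pair_d = dist[rows]
    pair_w = w[rows]
    # exclude self pairs
    self_mask = np.zeros((rows.size, k), dtype=bool)
    self_mask[np.arange(rows.size), rows] = True
    d_flat = pair_d[~self_mask]
    w_flat = pair_w[~self_mask]
    too_far = d_flat > 180.0 + 1e-9
    if np.any(too_far):
        first = np.argmax(too_far)
        raise OutOfRangeDistanceError(
            f"inter-node distance {d_flat[first]:.1f} mm exceeds 180 mm"
        )
    idx = _bin_index(d_flat)
    counts = np.bincount(idx, minlength=N_BINS).astype(int)
    sums = np.bincount(idx, weights=w_flat, minlength=N_BINS)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DistanceProfile(
        network=network,
        bin_edges=BIN_EDGES_MM.copy(),
        mean_strength=means,
        counts=counts,
        subject_id=subject_id,
        group=group,
    )


def binned_strength_auc(
    graphs: list[ThresholdedGraph],
    densities,
    dist: np.ndarray,
    parc: Parcellation,
    network: str,
    subject_id: str | None = None,
    group: str | None = None,
) -> DistanceProfile:
    """AUC-summarized distance profile across the admissible densities.

    Per-bin means are computed at each density and integrated over
    density with the trapezoid rule; a bin empty at any density is
    flagged missing.
    """
    from .topology import auc_over_densities

    densities = np.asarray(densities, dtype=float)
    profiles = [
        binned_strength(g, dist, parc, network) for g in graphs
    ]
    counts = profiles[0].counts
    means = np.full(N_BINS, np.nan)
    stacked = np.vstack([p.mean_strength for p in profiles])
    for b in range(N_BINS):
        col = stacked[:, b]
        if np.all(np.isfinite(col)):
            means[b] = auc_over_densities(col, densities)
    return DistanceProfile(
        network=network,
        bin_edges=BIN_EDGES_MM.copy(),
        mean_strength=means,
        counts=counts,
        subject_id=subject_id,
        group=group,
    )


@dataclass
class BinComparison:
    """One-way ANOVA result for a single distance bin."""

    bin_low: float
    bin_high: float
    f: float
    p: float
    tukey: dict[tuple[str, str], tuple[float, float]]


def groupwise_bin_anova(
    profiles: list[DistanceProfile],
    groups: list[str],
    with_tukey: bool = True,
) -> list[BinComparison]:
    """Per-bin one-way ANOVA across groups with Tukey HSD post-hoc.

    Bins missing (NaN) for any subject are skipped with a warning.
    Requires at least two groups with at least two subjects each.
    ``with_tukey=False`` skips the post-hoc contrasts (omnibus F only).
    """
    groups = [str(g) for g in groups]
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    members = {g: [i for i, gg in enumerate(groups) if gg == g] for g in names}
    if any(len(v) < 2 for v in members.values()):
        raise ValueError("every group needs at least two subjects")
    stacked = np.vstack([p.mean_strength for p in profiles])
    out: list[BinComparison] = []
    for b in range(N_BINS):
        col = stacked[:, b]
        if not np.all(np.isfinite(col)):
            warnings.warn(
                f"bin [{BIN_EDGES_MM[b]:.0f}, {BIN_EDGES_MM[b + 1]:.0f}) skipped: "
                "missing for at least one subject",
                BinSkippedWarning,
            )
            continue
        samples = [col[members[g]] for g in names]
        f, p = f_oneway(*samples)
        contrasts = {}
        if with_tukey:
            hsd = tukey_hsd(*samples)
            for a in range(len(names)):
                for c in range(a + 1, len(names)):
                    diff = float(np.mean(samples[a]) - np.mean(samples[c]))
                    contrasts[(names[a], names[c])] = (diff, float(hsd.pvalue[a, c]))
        out.append(
            BinComparison(
                bin_low=float(BIN_EDGES_MM[b]),
                bin_high=float(BIN_EDGES_MM[b + 1]),
                f=float(f),
                p=float(p),
                tukey=contrasts,
            )
        )
    return out
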