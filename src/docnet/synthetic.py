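"""Synthetic cohort generator.

Emulates the statistical structure of a resting-state fMRI study of
disorders of consciousness: a 264-node parcellation grouped into ten
functional networks (fronto-parietal FPN = 25 nodes, default-mode
DMN = 58 nodes), three groups (11 VS/UWS, 7 MCS, 11 controls), and
band-limited (0.01-0.08 Hz, TR = 2 s) nodal time series of 235 usable
timepoints.

Each subject's series are drawn from a zero-mean multivariate Gaussian
whose correlation matrix has a modular block structure (within-network
pairs more correlated than between-network pairs) plus group-dependent,
distance-dependent perturbations: long-range (> 75 mm) within-FPN pairs
are strengthened and short-range (< 40 mm) within-DMN pairs weakened, in
patients, with a larger perturbation in VS/UWS than in MCS and none in
controls.  Shared global/white-matter/CSF fluctuations, motion channels
and white observation noise are mixed in, and everything is band-limited
with the same filter the analysis uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from types import MappingProxyType
from typing import Mapping

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._seeds import derive_seed
from .connectivity import bandpass
from .errors import EmptyCohortError, GenerationError, InvalidPartitionError


class Group(str, Enum):
    """Conscious-state group label."""

    VS_UWS = "VS_UWS"
    MCS = "MCS"
    CONTROL = "CONTROL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Ten-network partition of 264 nodes.  Only the FPN (25) and DMN (58)
#: counts are pinned by the analysis; the remaining eight networks absorb
#: the rest of the nodes in round numbers.
DEFAULT_NETWORK_SIZES: Mapping[str, int] = MappingProxyType(
    {
        "SMN": 35,
        "CON": 26,
        "AUD": 13,
        "DMN": 58,
        "VIS": 31,
        "FPN": 25,
        "SAL": 18,
        "SUB": 17,
        "VAN": 20,
        "DAN": 21,
    }
)

#: Base correlation structure: within-network / between-network levels.
WITHIN_NETWORK_R = 0.30
BETWEEN_NETWORK_R = 0.05
#: Eigenvalue floor used to repair indefinite perturbed matrices.
EIGENVALUE_FLOOR = 1e-6
#: Maximum inter-node distance after rescaling (the distance binning
#: supports 0-180 mm; 170 mm leaves headroom).
MAX_SPAN_MM = 170.0


@dataclass
class Parcellation:
    """Spatially embedded node set with a network partition.

    Coordinates are MNI millimetres; each node belongs to exactly one of
    the named networks.
    """

    node_id: np.ndarray
    label: list[str]
    coords: np.ndarray
    network: np.ndarray

    @property
    def n_nodes(self) -> int:
        return int(self.node_id.size)

    @property
    def networks(self) -> list[str]:
        seen: dict[str, None] = {}
        for n in self.network:
            seen.setdefault(str(n), None)
        return list(seen)

    def network_sizes(self) -> dict[str, int]:
        return {n: int(np.sum(self.network == n)) for n in self.networks}

    def nodes_of(self, network: str) -> np.ndarray:
        idx = np.flatnonzero(self.network == network)
        if idx.size == 0:
            raise KeyError(f"unknown network {network!r}")
        return idx

    def validate(self) -> None:
        k = self.n_nodes
        if k < 10:
            raise InvalidPartitionError(f"need at least 10 nodes, got {k}")
        if self.coords.shape != (k, 3) or not np.all(np.isfinite(self.coords)):
            raise InvalidPartitionError("coordinates must be a finite K x 3 array")
        if len(self.label) != k or self.network.shape != (k,):
            raise InvalidPartitionError("label/network lengths inconsistent")
        if sum(self.network_sizes().values()) != k:
            raise InvalidPartitionError("per-network counts do not sum to K")


@dataclass
class SubjectRecord:
    """One subject: group label, nodal series and confound channels.

    ``timeseries`` is nodes x T; ``confounds`` is channels x T with rows
    ordered (global, white matter, CSF, six motion channels).
    """

    subject_id: str
    group: Group
    timeseries: np.ndarray
    confounds: np.ndarray

    @property
    def n_timepoints(self) -> int:
        return int(self.timeseries.shape[1])


def _default_multipliers() -> dict[Group, float]:
    # VS/UWS expresses the full +/-0.15 perturbation; MCS 0.08/0.15 of it,
    # giving the monotone ordering VS/UWS > MCS > control.
    return {Group.VS_UWS: 1.0, Group.MCS: 0.08 / 0.15, Group.CONTROL: 0.0}


@dataclass(frozen=True)
class EffectSpec:
    """Planted group x distance covariance perturbation.

    ``fpn_long_gain`` is added to within-FPN correlations of node pairs
    farther apart than ``long_threshold_mm``; ``dmn_short_loss`` is
    subtracted from within-DMN correlations of pairs closer than
    ``short_threshold_mm``.  Both are scaled by the per-group multiplier
    (control fixed at 0).
    """

    fpn_long_gain: float = 0.15
    dmn_short_loss: float = 0.15
    group_multipliers: Mapping[Group, float] = field(
        default_factory=_default_multipliers
    )
    long_threshold_mm: float = 75.0
    short_threshold_mm: float = 40.0
    #: Relative SD of the per-patient severity factors: within a patient
    #: group, the expressed perturbation is the group multiplier times a
    #: subject-specific factor max(0, 1 + N(0, severity_jitter^2)),
    #: emulating clinical heterogeneity of impairment.  The FPN and DMN
    #: factors are correlated at ``network_jitter_corr`` — the two
    #: networks' disruptions track overall severity but are expressed
    #: partly independently.
    severity_jitter: float = 0.20
    network_jitter_corr: float = 0.5
    noise_sd: float = 0.15
    global_strength: float = 0.15
    wm_strength: float = 0.10
    csf_strength: float = 0.10
    motion_leak: float = 0.02
    seed: int = 0

    def multiplier(self, group: Group) -> float:
        m = dict(self.group_multipliers)
        if Group.CONTROL in m and m[Group.CONTROL] != 0.0:
            raise ValueError("CONTROL multiplier must be 0")
        return float(m.get(Group(group), 0.0))


def null_effect(seed: int = 0) -> EffectSpec:
    """EffectSpec with all group multipliers zero (no planted effect)."""
    return EffectSpec(
        group_multipliers={g: 0.0 for g in Group},
        seed=seed,
    )


def make_parcellation(
    network_sizes: Mapping[str, int] | None = None,
    spread_mm: float = 13.0,
    seed: int = 0,
    four_locus_networks: tuple[str, ...] = ("FPN",),
) -> Parcellation:
    """Generate a spatially clustered parcellation.

    Each network is a set of mirrored Gaussian sub-clusters, like
    large-scale rs-fMRI networks: by default one locus per hemisphere,
    so within-network pair distances span both the short (same locus)
    and the long (cross-hemisphere) range.  Networks named in
    ``four_locus_networks`` get four loci (bilateral anterior and
    posterior, the fronto-parietal DLPFC + PPC layout), which makes
    most of their within-network pairs long-range.  All coordinates
    are rescaled down when the largest inter-node distance exceeds
    ``MAX_SPAN_MM``, so pairwise distances span 0-180 mm.
    Deterministic for a fixed seed.
    """
    sizes = dict(DEFAULT_NETWORK_SIZES if network_sizes is None else network_sizes)
    if any(c <= 0 for c in sizes.values()):
        raise InvalidPartitionError("network counts must be positive")
    if spread_mm <= 0:
        raise InvalidPartitionError("spread_mm must be positive")
    if len(sizes) < 1:
        raise InvalidPartitionError("at least one network required")

    rng = np.random.default_rng(seed)
    coords, labels, nets = [], [], []
    for name, count in sizes.items():
        centre_yz = rng.normal(0.0, 22.0, size=2)
        lateral = rng.uniform(45.0, 60.0)
        if name in four_locus_networks:
            ant = rng.uniform(35.0, 50.0)
            loci = np.array(
                [
                    [lateral, centre_yz[0] + ant, centre_yz[1]],
                    [-lateral, centre_yz[0] + ant, centre_yz[1]],
                    [lateral, centre_yz[0] - ant, centre_yz[1]],
                    [-lateral, centre_yz[0] - ant, centre_yz[1]],
                ]
            )
        else:
            loci = np.array(
                [
                    [lateral, centre_yz[0], centre_yz[1]],
                    [-lateral, centre_yz[0], centre_yz[1]],
                ]
            )
        centre = loci[np.arange(count) % loci.shape[0]]
        pts = centre + rng.normal(0.0, spread_mm, size=(count, 3))
        coords.append(pts)
        labels.extend(f"{name}_{k:03d}" for k in range(count))
        nets.extend([name] * count)
    xyz = np.vstack(coords)
    span = float(pdist(xyz).max()) if xyz.shape[0] > 1 else 0.0
    if span > MAX_SPAN_MM:
        xyz = xyz * (MAX_SPAN_MM / span)
    parc = Parcellation(
        node_id=np.arange(xyz.shape[0]),
        label=labels,
        coords=xyz,
        network=np.asarray(nets, dtype=object),
    )
    if len(sizes) >= 2 and parc.n_nodes >= 10:
        parc.validate()
    return parc


def power264_parcellation() -> Parcellation:
    """Parcellation on the published 264 meta-analytic MNI coordinates.

    Node coordinates are the published 264-region centres (loaded from
    nilearn's packaged copy).  The per-region network assignment table is
    not redistributable here, so the ten network labels are a synthetic
    reconstruction assigned in blocks of the published per-network sizes
    (fronto-parietal 25 nodes, default-mode 58 nodes); only the counts,
    not the individual memberships, are faithful.
    """
    from nilearn import datasets  # local import: optional dependency

    rois = datasets.fetch_coords_power_2011().rois
    xyz = rois[["x", "y", "z"]].to_numpy(dtype=float)
    nets: list[str] = []
    labels: list[str] = []
    for name, count in DEFAULT_NETWORK_SIZES.items():
        nets.extend([name] * count)
        labels.extend(f"{name}_{k:03d}" for k in range(count))
    if len(nets) != xyz.shape[0]:
        raise InvalidPartitionError(
            f"network sizes sum to {len(nets)}, expected {xyz.shape[0]}"
        )
    parc = Parcellation(
        node_id=np.arange(xyz.shape[0]),
        label=labels,
        coords=xyz,
        network=np.asarray(nets, dtype=object),
    )
    parc.validate()
    return parc


def _floor_eigenvalues(cov: np.ndarray, floor: float = EIGENVALUE_FLOOR) -> np.ndarray:
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    vals = np.maximum(vals, floor)
    out = (vecs * vals) @ vecs.T
    return (out + out.T) / 2.0


def signal_covariance(
    parc: Parcellation,
    group: Group,
    fx: EffectSpec,
    multiplier: float | None = None,
    multiplier_dmn: float | None = None,
) -> np.ndarray:
    """Covariance of the network-structured signal component.

    Modular base (within-network 0.30, between-network 0.05, unit
    variances) plus the group-scaled distance-dependent FPN/DMN
    perturbations, repaired to be symmetric positive definite by
    eigenvalue flooring.  ``multiplier`` overrides the group multiplier
    for the FPN perturbation (and for the DMN one unless
    ``multiplier_dmn`` is also given) — used for per-subject severity.
    """
    net = parc.network
    same = net[:, None] == net[None, :]
    cov = np.where(same, WITHIN_NETWORK_R, BETWEEN_NETWORK_R)
    np.fill_diagonal(cov, 1.0)
    m_fpn = fx.multiplier(Group(group)) if multiplier is None else multiplier
    m_dmn = m_fpn if multiplier_dmn is None else multiplier_dmn
    if m_fpn != 0.0 or m_dmn != 0.0:
        dist = squareform(pdist(parc.coords))
        nets = set(parc.networks)
        if "FPN" in nets and m_fpn != 0.0:
            fpn = net == "FPN"
            mask = np.outer(fpn, fpn) & (dist > fx.long_threshold_mm)
            cov = cov + m_fpn * fx.fpn_long_gain * mask
        if "DMN" in nets and m_dmn != 0.0:
            dmn = net == "DMN"
            mask = (
                np.outer(dmn, dmn)
                & (dist < fx.short_threshold_mm)
                & ~np.eye(parc.n_nodes, dtype=bool)
            )
            cov = cov - m_dmn * fx.dmn_short_loss * mask
    np.fill_diagonal(cov, 1.0)
    cov = _floor_eigenvalues(cov)
    return cov


def target_covariance(parc: Parcellation, group: Group, fx: EffectSpec) -> np.ndarray:
    """Model covariance of the generated nodal series.

    Signal covariance plus the rank-one contributions of the shared
    global/white-matter/CSF/motion channels and the white-noise diagonal.
    The sample correlation matrix of a long simulated run converges to
    the correlation form of this matrix.
    """
    cov = signal_covariance(parc, group, fx).copy()
    shared = (
        fx.global_strength**2
        + fx.wm_strength**2
        + fx.csf_strength**2
        + 6 * fx.motion_leak**2
    )
    cov += shared
    cov[np.diag_indices_from(cov)] += fx.noise_sd**2
    return cov


def simulate_subject(
    parc: Parcellation,
    group: Group,
    fx: EffectSpec | None = None,
    T: int = 235,
    seed: int = 0,
    tr_s: float = 2.0,
    subject_id: str | None = None,
) -> SubjectRecord:
    """Draw one subject's band-limited nodal series and confounds.

    T independent samples of the multivariate Gaussian signal are mixed
    with shared global/WM/CSF fluctuations, six motion channels and white
    noise, then band-limited to 0.01-0.08 Hz at the given sampling
    interval.  Because every node passes through the same linear filter,
    the inter-node correlation structure of ``target_covariance`` is
    preserved.
    """
    if T < 3:
        raise ValueError(f"T must be >= 3, got {T}")
    fx = fx or EffectSpec()
    group = Group(group)
    rng = np.random.default_rng(seed)
    m = fx.multiplier(group)
    m_fpn = m_dmn = m
    if m != 0.0 and fx.severity_jitter > 0.0:
        rho = float(np.clip(fx.network_jitter_corr, 0.0, 1.0))
        shared = rng.standard_normal()
        own = rng.standard_normal(2)
        j = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        m_fpn = m * max(0.0, 1.0 + fx.severity_jitter * j[0])
        m_dmn = m * max(0.0, 1.0 + fx.severity_jitter * j[1])
    cov = signal_covariance(
        parc, group, fx, multiplier=m_fpn, multiplier_dmn=m_dmn
    )
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - flooring guards
        raise GenerationError("covariance not positive definite after flooring") from exc
    k = parc.n_nodes
    x = chol @ rng.standard_normal((k, T))

    g = rng.standard_normal(T)
    wm = rng.standard_normal(T)
    csf = rng.standard_normal(T)
    motion = rng.standard_normal((6, T))
    x = (
        x
        + fx.global_strength * g
        + fx.wm_strength * wm
        + fx.csf_strength * csf
        + fx.motion_leak * motion.sum(axis=0)
    )
    x = x + fx.noise_sd * rng.standard_normal((k, T))

    x = bandpass(x, tr_s=tr_s)
    # Confound rows record the injected nuisance series themselves (what an
    # ideal global/WM/CSF/motion extraction would recover), band-limited the
    # same way as the data they contaminate.
    confounds = bandpass(np.vstack([g, wm, csf, motion]), tr_s=tr_s)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(confounds))):
        raise GenerationError("non-finite values in generated series")
    return SubjectRecord(
        subject_id=subject_id or f"sub-{group.value}-{seed}",
        group=group,
        timeseries=x,
        confounds=confounds,
    )


def simulate_cohort(
    n_vs: int = 11,
    n_mcs: int = 7,
    n_ctrl: int = 11,
    fx: EffectSpec | None = None,
    seed: int = 0,
    parc: Parcellation | None = None,
    T: int = 235,
    tr_s: float = 2.0,
) -> tuple[Parcellation, list[SubjectRecord]]:
    """Simulate a labelled cohort, ordered VS/UWS, MCS, CONTROL.

    Per-subject seeds are derived deterministically from the cohort seed,
    so the same seed reproduces the identical cohort.
    """
    if min(n_vs, n_mcs, n_ctrl) < 0:
        raise ValueError("group sizes must be non-negative")
    if n_vs + n_mcs + n_ctrl == 0:
        raise EmptyCohortError("all group sizes are zero")
    fx = fx or EffectSpec()
    if parc is None:
        parc = make_parcellation(seed=derive_seed(seed, "parcellation"))
    subjects: list[SubjectRecord] = []
    index = 0
    for group, count in (
        (Group.VS_UWS, n_vs),
        (Group.MCS, n_mcs),
        (Group.CONTROL, n_ctrl),
    ):
        for k in range(count):
            subjects.append(
                simulate_subject(
                    parc,
                    group,
                    fx,
                    T=T,
                    seed=derive_seed(seed, "subject", index),
                    tr_s=tr_s,
                    subject_id=f"sub-{group.value}-{k + 1:02d}",
                )
            )
            index += 1
    return parc, subjects
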