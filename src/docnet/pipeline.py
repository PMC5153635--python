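"""End-to-end orchestration of the analysis.

simulate -> connectivity -> density thresholding -> topology ->
distance profiles -> classification -> group statistics, from a single
config and one master seed.  Every stage derives its own random stream
from the master seed, so a fixed config yields byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import distance as dist_mod
from . import graphs, io, mvpa, stats, topology
from ._seeds import derive_seed
from .errors import ConfigError
from .synthetic import EffectSpec, Group, simulate_cohort

log = logging.getLogger("docnet")


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, serializable round-trip identical."""

    out_dir: str = "docnet-out"
    n_vs: int = 11
    n_mcs: int = 7
    n_ctrl: int = 11
    #: None -> the default 264-node / 10-network partition.
    network_sizes: dict[str, int] | None = None
    T: int = 235
    tr_s: float = 2.0
    low_hz: float = 0.01
    high_hz: float = 0.08
    density_start: float = 0.025
    density_stop: float = 0.325
    density_step: float = 0.02
    admissibility: str = "grid"  # "grid": published range; "criteria": re-derive
    n_topology_nulls: int = 100
    n_mvpa_perm: int = 1000
    n_nodal_perm: int = 10000
    classify_networks: tuple[str, ...] = ("FPN", "DMN")
    metrics: tuple[str, ...] = topology.METRICS
    normalize_metrics: tuple[str, ...] = ("strength", "betweenness")
    feature_normalized: bool = True
    write_intermediates: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_vs + self.n_mcs + self.n_ctrl <= 0:
            raise ConfigError("cohort is empty")
        if self.n_topology_nulls <= 0 or self.n_mvpa_perm <= 0 or self.n_nodal_perm <= 0:
            raise ConfigError("null/permutation counts must be positive")
        nyq = 1.0 / (2.0 * self.tr_s)
        if not (0 < self.low_hz < self.high_hz < nyq):
            raise ConfigError("invalid filter band")
        if self.density_step <= 0 or not (
            0 < self.density_start <= self.density_stop <= 1
        ):
            raise ConfigError("invalid density grid")
        if self.admissibility not in ("grid", "criteria"):
            raise ConfigError("admissibility must be 'grid' or 'criteria'")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        payload = json.loads(text)
        for key in ("classify_networks", "metrics", "normalize_metrics"):
            payload[key] = tuple(payload[key])
        return cls(**payload)

    def content_hash(self) -> str:
        """Hash of the scientific parameters (paths excluded)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        payload.pop("write_intermediates", None)
        token = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(token.encode()).hexdigest()[:16]


def _setup_logging(out: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(name)s: %(message)s"))
        log.addHandler(stream)
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            log.removeHandler(h)
    fh = logging.FileHandler(out / "run.log", mode="a")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and write) the results report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    (out / "config.json").write_text(config.to_json())
    chash = config.content_hash()
    log.info("pipeline start, config hash %s, seed %d", chash, config.seed)

    # -- stage: cohort -------------------------------------------------------
    fx = EffectSpec(seed=derive_seed(config.seed, "effects"))
    parc = None
    if config.network_sizes is not None:
        from .synthetic import make_parcellation

        parc = make_parcellation(
            config.network_sizes, seed=derive_seed(config.seed, "parcellation")
        )
    parc, subjects = simulate_cohort(
        config.n_vs,
        config.n_mcs,
        config.n_ctrl,
        fx=fx,
        seed=derive_seed(config.seed, "cohort"),
        parc=parc,
        T=config.T,
        tr_s=config.tr_s,
    )
    groups = [str(s.group) for s in subjects]
    log.info("cohort: %d subjects (%s)", len(subjects), ", ".join(sorted(set(groups))))
    if config.write_intermediates:
        io.write_cohort(parc, subjects, out / "cohort", params={"hash": chash})

    # -- stage: connectivity (cached by config hash) ------------------------
    conn_dir = out / "connectivity"
    matrices = []
    for rec in subjects:
        cpath = conn_dir / f"{rec.subject_id}_z.tsv"
        cached = None
        if cpath.exists():
            try:
                meta = io.read_sidecar(cpath)
                if meta.get("hash") == chash:
                    cached = io.read_connectivity(cpath)
            except Exception:
                cached = None
        if cached is None:
            cached = conn.subject_connectivity(
                rec, low_hz=config.low_hz, high_hz=config.high_hz, tr_s=config.tr_s
            )
            if config.write_intermediates:
                conn_dir.mkdir(parents=True, exist_ok=True)
                io.write_connectivity(cached, cpath, params={"hash": chash})
        matrices.append(cached)
    log.info("connectivity: %d matrices", len(matrices))

    # -- stage: density grid -------------------------------------------------
    grid = graphs.density_grid(
        config.density_start, config.density_stop, config.density_step
    )
    if config.admissibility == "criteria":
        per_subject = [
            graphs.select_density_range(
                c,
                grid,
                null_count=config.n_topology_nulls,
                seed=derive_seed(config.seed, "admissibility", i),
            )
            for i, c in enumerate(matrices)
        ]
        grid = graphs.intersect_admissible(per_subject)
    log.info(
        "density grid: %d of %d densities admissible",
        int(grid.admissible.sum()),
        len(grid),
    )

    # -- stage: topology -----------------------------------------------------
    profiles = [
        topology.subject_topology(
            c,
            grid,
            parc=parc,
            n_nulls=config.n_topology_nulls,
            seed=derive_seed(config.seed, "topology", i),
            metrics=config.metrics,
            normalized=config.feature_normalized,
            normalize_metrics=config.normalize_metrics,
        )
        for i, c in enumerate(matrices)
    ]
    log.info("topology: %d profiles over %d densities", len(profiles),
             grid.admissible.sum())

    # -- stage: network-level statistics ------------------------------------
    network_stats: dict[str, dict] = {}
    patients = [i for i, g in enumerate(groups) if g != str(Group.CONTROL)]
    controls = [i for i, g in enumerate(groups) if g == str(Group.CONTROL)]
    for metric in config.metrics:
        table = pd.DataFrame(
            [
                {
                    "subject": prof.subject_id,
                    "state": g,
                    "network": net,
                    "value": val,
                }
                for prof, g in zip(profiles, groups)
                for net, val in prof.network_auc[metric].items()
            ]
        )
        aov = stats.two_way_anova(table)
        entry = {
            "anova": {
                name: {"F": r.f, "df": list(r.df), "p": r.p}
                for name, r in aov.items()
            },
            "tukey": {},
        }
        for net in ("FPN", "DMN"):
            vals = np.array(
                [prof.network_auc[metric][net] for prof in profiles]
            )
            entry["tukey"][net] = {
                f"{a} vs {b}": {"diff": d, "p": p}
                for (a, b), (d, p) in stats.tukey_posthoc(vals, groups).items()
            }
        if patients and controls:
            fpn = np.array([profiles[i].network_auc[metric]["FPN"] for i in patients])
            dmn = np.array([profiles[i].network_auc[metric]["DMN"] for i in patients])
            fpn_c = float(
                np.mean([profiles[i].network_auc[metric]["FPN"] for i in controls])
            )
            dmn_c = float(
                np.mean([profiles[i].network_auc[metric]["DMN"] for i in controls])
            )
            r, p, pb = stats.baseline_correlation(fpn, dmn, fpn_c, dmn_c, m_comparisons=3)
            entry["fpn_dmn_correlation"] = {"r": r, "p": p, "p_bonferroni": pb}
        network_stats[metric] = entry

    # -- stage: distance profiles --------------------------------------------
    dist = dist_mod.distance_matrix(parc)
    densities = grid.admissible_densities
    distance_results: dict[str, list] = {}
    dist_profiles: dict[str, list] = {}
    for net in ("FPN", "DMN"):
        if net not in parc.networks:
            continue
        per_subject = []
        for c, g in zip(matrices, groups):
            gs = [graphs.threshold_by_density(c, float(d)) for d in densities]
            per_subject.append(
                dist_mod.binned_strength_auc(
                    gs, densities, dist, parc, net,
                    subject_id=c.subject_id, group=g,
                )
            )
        dist_profiles[net] = per_subject
        comparisons = dist_mod.groupwise_bin_anova(per_subject, groups)
        distance_results[net] = [
            {
                "bin_low": c.bin_low,
                "bin_high": c.bin_high,
                "F": c.f,
                "p": c.p,
            }
            for c in comparisons
        ]
    log.info("distance: %d networks profiled", len(distance_results))

    # -- stage: classification ----------------------------------------------
    classification: dict[str, dict] = {}
    single_nets = [(net,) for net in config.classify_networks]
    combos = single_nets + [tuple(config.classify_networks)]
    y = np.asarray(groups, dtype=object)
    for combo in combos:
        fm = mvpa.build_features(
            profiles, parc, list(combo), normalized=config.feature_normalized
        )
        p, acc, _ = mvpa.permutation_pvalue(
            fm.X,
            fm.y,
            n_perm=config.n_mvpa_perm,
            seed=derive_seed(config.seed, "mvpa", "+".join(combo)),
        )
        classification["+".join(combo)] = {
            "accuracy_pct": acc,
            "permutation_p": p,
            "chance_pct": 100.0 / len(set(groups)),
        }
    combined = tuple(config.classify_networks)
    fm_all = mvpa.build_features(
        profiles, parc, list(combined), normalized=config.feature_normalized
    )
    pairs = [
        (str(Group.VS_UWS), str(Group.CONTROL)),
        (str(Group.MCS), str(Group.CONTROL)),
        (str(Group.VS_UWS), str(Group.MCS)),
    ]
    for a, b in pairs:
        keep = np.isin(y, [a, b])
        if keep.sum() < 3 or len(set(y[keep])) < 2:
            continue
        rep = mvpa.loocv(fm_all.X[keep], y[keep])
        p, acc, _ = mvpa.permutation_pvalue(
            fm_all.X[keep],
            y[keep],
            n_perm=config.n_mvpa_perm,
            seed=derive_seed(config.seed, "mvpa-binary", a, b),
        )
        classification[f"{a} vs {b}"] = {
            "accuracy_pct": acc,
            "sensitivity_pct": rep.sensitivity_pct,
            "specificity_pct": rep.specificity_pct,
            "positive_class": rep.positive_class,
            "permutation_p": p,
            "chance_pct": 50.0,
        }
    model = mvpa.train_ovr(fm_all.X, fm_all.y)
    weight_map = mvpa.nodal_weight_map(model, fm_all.feature_index)
    log.info("classification: %d runs", len(classification))

    # -- stage: nodal permutation test ---------------------------------------
    node_ids = np.concatenate([parc.nodes_of(net) for net in combined])
    data = np.stack(
        [
            np.stack(
                [
                    prof.feature_values(m, normalized=config.feature_normalized)[node_ids]
                    for m in config.metrics
                ],
                axis=1,
            )
            for prof in profiles
        ]
    )
    nodal = stats.nodal_permutation_test(
        data,
        groups,
        node_ids=node_ids,
        n_perm=config.n_nodal_perm,
        seed=derive_seed(config.seed, "nodal"),
    )

    report = {
        "config_hash": chash,
        "seed": config.seed,
        "n_subjects": len(subjects),
        "admissible_densities": [float(d) for d in densities],
        "network_stats": network_stats,
        "distance": distance_results,
        "classification": classification,
        "nodal_weight_map": {str(k): v for k, v in weight_map.items()},
        "nodal_test": {
            "node_id": nodal.node_id.tolist(),
            "f_avg": nodal.f_avg.tolist(),
            "p": nodal.p.tolist(),
            "q": nodal.q.tolist(),
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("report written to %s", out / "report.json")
    return report
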