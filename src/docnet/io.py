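"""Plain-text serialization of every pipeline artifact.

All numeric files are TSV with floats printed at 17 significant digits
(so write-then-read round-trips are bit exact); each numeric output can
carry a JSON sidecar recording the parameters that produced it.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .connectivity import ConnectivityMatrix
from .errors import ParseError
from .graphs import ThresholdedGraph
from .mvpa import ClassificationReport, FeatureMatrix
from .synthetic import Group, Parcellation, SubjectRecord

FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def write_sidecar(path: str | Path, params: dict) -> Path:
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(params, indent=2, sort_keys=True, default=str))
    return side


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(str(path) + ".json").read_text())


# -- parcellation -----------------------------------------------------------

PARC_COLUMNS = ["node_id", "label", "x_mm", "y_mm", "z_mm", "network"]


def write_parcellation(parc: Parcellation, path: str | Path) -> Path:
    path = Path(path)
    lines = ["\t".join(PARC_COLUMNS)]
    for k in range(parc.n_nodes):
        x, y, z = parc.coords[k]
        lines.append(
            "\t".join(
                [
                    str(int(parc.node_id[k])),
                    parc.label[k],
                    _fmt(x),
                    _fmt(y),
                    _fmt(z),
                    str(parc.network[k]),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def read_parcellation(path: str | Path) -> Parcellation:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != PARC_COLUMNS:
        raise ParseError(f"{path}: line 1: expected header {'	'.join(PARC_COLUMNS)}")
    ids, labels, coords, nets = [], [], [], []
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(f"{path}: line {ln}: expected 6 fields, got {len(fields)}")
        try:
            ids.append(int(fields[0]))
            coords.append([float(fields[2]), float(fields[3]), float(fields[4])])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: {exc}") from None
        labels.append(fields[1])
        nets.append(fields[5])
    return Parcellation(
        node_id=np.asarray(ids),
        label=labels,
        coords=np.asarray(coords, dtype=float),
        network=np.asarray(nets, dtype=object),
    )


# -- matrices ----------------------------------------------------------------


def write_matrix(mat: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, np.atleast_2d(mat), fmt=FLOAT_FMT, delimiter="\t")
    return path


def read_matrix(path: str | Path) -> np.ndarray:
    lines = Path(path).read_text().splitlines()
    rows = []
    width = None
    for ln, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise ParseError(
                f"{path}: line {ln}: expected {width} fields, got {len(fields)}"
            )
        try:
            rows.append([float(f) for f in fields])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: {exc}") from None
    if not rows:
        raise ParseError(f"{path}: line 1: empty matrix file")
    return np.asarray(rows, dtype=float)


# -- cohort ------------------------------------------------------------------


def write_cohort(
    parc: Parcellation,
    subjects: list[SubjectRecord],
    out_dir: str | Path,
    params: dict | None = None,
) -> Path:
    """Write parcellation, per-subject series/confounds and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_parcellation(parc, out / "parcellation.tsv")
    manifest = {"parcellation": "parcellation.tsv", "subjects": []}
    for rec in subjects:
        ts = f"{rec.subject_id}_timeseries.tsv"
        cf = f"{rec.subject_id}_confounds.tsv"
        write_matrix(rec.timeseries, out / ts)
        write_matrix(rec.confounds, out / cf)
        manifest["subjects"].append(
            {
                "subject_id": rec.subject_id,
                "group": str(rec.group),
                "timeseries": ts,
                "confounds": cf,
            }
        )
    path = out / "cohort.json"
    path.write_text(json.dumps(manifest, indent=2))
    if params:
        write_sidecar(path, params)
    return path


def read_cohort(manifest_path: str | Path) -> tuple[Parcellation, list[SubjectRecord]]:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    parc = read_parcellation(base / manifest["parcellation"])
    subjects = []
    for entry in manifest["subjects"]:
        subjects.append(
            SubjectRecord(
                subject_id=entry["subject_id"],
                group=Group(entry["group"]),
                timeseries=read_matrix(base / entry["timeseries"]),
                confounds=read_matrix(base / entry["confounds"]),
            )
        )
    return parc, subjects


# -- connectivity ------------------------------------------------------------


def write_connectivity(
    c: ConnectivityMatrix, path: str | Path, params: dict | None = None
) -> Path:
    path = write_matrix(c.z, path)
    write_sidecar(
        path,
        {"subject_id": c.subject_id, "group": c.group, **(params or {})},
    )
    return path


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    z = read_matrix(path)
    meta = read_sidecar(path)
    c = ConnectivityMatrix(z=z, subject_id=meta.get("subject_id"), group=meta.get("group"))
    c.validate()
    return c


# -- thresholded graphs ------------------------------------------------------


def write_graph(g: ThresholdedGraph, path: str | Path) -> Path:
    """Sparse edge-list TSV (i, j, weight) with a JSON header sidecar."""
    path = Path(path)
    i, j, w = g.edge_list()
    lines = ["\t".join(["i", "j", "weight"])]
    for a, b, x in zip(i.tolist(), j.tolist(), w.tolist()):
        lines.append(f"{a}\t{b}\t{_fmt(x)}")
    path.write_text("\n".join(lines) + "\n")
    write_sidecar(path, {"K": g.n_nodes, "density": g.density})
    return path


def read_graph(path: str | Path) -> ThresholdedGraph:
    meta = read_sidecar(path)
    k = int(meta["K"])
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != ["i", "j", "weight"]:
        raise ParseError(f"{path}: line 1: expected header i\tj\tweight")
    w = np.zeros((k, k))
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(f"{path}: line {ln}: expected 3 fields, got {len(fields)}")
        try:
            a, b, x = int(fields[0]), int(fields[1]), float(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: {exc}") from None
        w[a, b] = x
        w[b, a] = x
    return ThresholdedGraph(weights=w, density=float(meta["density"]))


# -- features / reports ------------------------------------------------------


def write_features(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    header = ["subject_id", "group"] + [
        f"{net}:{node}:{metric}" for net, node, metric in fm.feature_index
    ]
    ids = fm.subject_ids or [f"s{i}" for i in range(fm.X.shape[0])]
    lines = ["\t".join(header)]
    for sid, label, row in zip(ids, fm.y, fm.X):
        lines.append("\t".join([str(sid), str(label)] + [_fmt(v) for v in row]))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_features(path: str | Path) -> FeatureMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: line 1: empty feature file")
    header = lines[0].split("\t")
    if header[:2] != ["subject_id", "group"]:
        raise ParseError(f"{path}: line 1: expected subject_id/group columns")
    index = []
    for col in header[2:]:
        net, node, metric = col.split(":")
        index.append((net, int(node), metric))
    ids, labels, rows = [], [], []
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}: line {ln}: expected {len(header)} fields, got {len(fields)}"
            )
        ids.append(fields[0])
        labels.append(fields[1])
        try:
            rows.append([float(f) for f in fields[2:]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {ln}: {exc}") from None
    return FeatureMatrix(
        X=np.asarray(rows, dtype=float),
        y=np.asarray(labels, dtype=object),
        feature_index=index,
        subject_ids=ids,
    )


def write_report(report: ClassificationReport, path: str | Path) -> Path:
    path = Path(path)
    payload = asdict(report)
    if isinstance(report.nodal_weights, np.ndarray):
        payload["nodal_weights"] = report.nodal_weights.tolist()
    elif isinstance(report.nodal_weights, dict):
        payload["nodal_weights"] = {str(k): float(v) for k, v in report.nodal_weights.items()}
    payload["per_class"] = {k: list(v) for k, v in report.per_class.items()}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=float))
    return path
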