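"""Multivariate pattern classification of conscious state.

Feature vectors concatenate the three nodal topological metrics
(strength, betweenness, degree) of every node in the selected networks.
One linear SVM is trained per class one-versus-rest; a held-out subject
is assigned the class with the maximal decision score (loss-based
decoding reduces to argmax for this design).  Performance is evaluated
by leave-one-out cross-validation and its significance by a permutation
test that relabels subjects and re-runs the full LOOCV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from ._seeds import derive_seed
from .synthetic import Parcellation

FEATURE_METRICS = ("strength", "betweenness", "degree")

#: Severity ranking used to pick the "positive" class of binary runs:
#: sensitivity is the proportion of the more-impaired group correctly
#: classified, specificity the proportion of the less-impaired group.
_SEVERITY = {"CONTROL": 0, "MCS": 1, "VS_UWS": 2}


@dataclass
class FeatureMatrix:
    """Subjects x features design with a bijective feature index."""

    X: np.ndarray
    y: np.ndarray
    feature_index: list[tuple[str, int, str]]  # (network, node_id, metric)
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.feature_index):
            raise ValueError("feature index does not match design width")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")
        if len(set(self.feature_index)) != len(self.feature_index):
            raise ValueError("feature index is not bijective")


def build_features(
    profiles: list,
    parc: Parcellation,
    networks: list[str],
    normalized: bool = True,
    per_density: bool = False,
) -> FeatureMatrix:
    """Concatenate nodal metrics over the given networks.

    Feature order is deterministic: networks in the given order, nodes by
    ascending node id, metrics in the order strength, betweenness,
    degree.  Default features are the AUC summaries across the
    admissible densities; ``per_density=True`` instead concatenates the
    per-density values (metric names gain a ``@density`` suffix).
    """
    index: list[tuple[str, int, str]] = []
    cols: list[tuple[int, str, int | None]] = []
    densities = profiles[0].densities if profiles else np.array([])
    for net in networks:
        for node in sorted(parc.nodes_of(net).tolist()):
            for metric in FEATURE_METRICS:
                if per_density:
                    for di, d in enumerate(densities):
                        index.append((net, int(node), f"{metric}@{d:g}"))
                        cols.append((int(node), metric, di))
                else:
                    index.append((net, int(node), metric))
                    cols.append((int(node), metric, None))
    rows = []
    labels = []
    ids = []
    for prof in profiles:
        vals = {}
        for metric in FEATURE_METRICS:
            if metric not in prof.nodal_auc:
                raise ValueError(
                    f"subject {prof.subject_id!r} is missing metric {metric!r}"
                )
            if per_density:
                vals[metric] = prof.normalized[metric] if normalized else prof.raw[metric]
            else:
                vals[metric] = prof.feature_values(metric, normalized=normalized)
        rows.append(
            [
                vals[m][n] if di is None else vals[m][di, n]
                for n, m, di in cols
            ]
        )
        labels.append(str(prof.group))
        ids.append(prof.subject_id)
    return FeatureMatrix(
        X=np.asarray(rows, dtype=float),
        y=np.asarray(labels, dtype=object),
        feature_index=index,
        subject_ids=ids,
    )


class _MirrorSVM:
    """Negated view of a fitted binary SVM (the other one-vs-rest side)."""

    def __init__(self, base: SVC):
        self._base = base

    @property
    def coef_(self):
        return -self._base.coef_

    def decision_function(self, X):
        return -self._base.decision_function(X)


@dataclass
class OvrModel:
    """One-vs-rest linear SVMs sharing a training-fold standardization."""

    classes: list[str]
    models: list[SVC]
    mean: np.ndarray
    scale: np.ndarray

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.atleast_2d(X) - self.mean) / self.scale
        return np.column_stack([m.decision_function(Xs) for m in self.models])

    def coefs(self) -> np.ndarray:
        """(n_classes, n_features) hyperplane weights in standardized space."""
        return np.vstack([m.coef_.ravel() for m in self.models])


def train_ovr(
    X: np.ndarray,
    y: np.ndarray,
    C_reg: float = 1.0,
    standardize: bool = True,
    classes: list[str] | None = None,
) -> OvrModel:
    """Train one linear SVM per class against the rest.

    Features are z-scored with training statistics (zero-variance columns
    get unit scale); each classifier sees +1 for its class, -1 otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y], dtype=object)
    if classes is None:
        classes = sorted(set(y))
    for cls in classes:
        if not np.any(y == cls):
            raise ValueError(f"class {cls!r} absent from training data")
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0, 1.0, scale)
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale
    models: list = []
    if len(classes) == 2:
        # the rest-vs-class SVM is the exact mirror of class-vs-rest, so a
        # single fit yields both one-vs-rest classifiers
        svm = SVC(kernel="linear", C=C_reg)
        svm.fit(Xs, np.where(y == classes[0], 1, -1))
        models = [svm, _MirrorSVM(svm)]
    else:
        for cls in classes:
            target = np.where(y == cls, 1, -1)
            svm = SVC(kernel="linear", C=C_reg)
            svm.fit(Xs, target)
            models.append(svm)
    return OvrModel(classes=list(classes), models=models, mean=mean, scale=scale)


def decode(scores) -> int:
    """Index of the maximal decision score; ties go to the lowest index."""
    s = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(s)):
        raise ValueError("non-finite decision scores")
    return int(np.argmax(s))  # argmax returns the first (lowest) maximizer


@dataclass
class ClassificationReport:
    """LOOCV predictions and the derived performance bookkeeping."""

    subjects: list[str]
    truth: list[str]
    predictions: list[str]
    classes: list[str]
    accuracy_pct: float
    per_class: dict[str, tuple[int, int]]  # class -> (correct, total)
    sensitivity_pct: float | None = None
    specificity_pct: float | None = None
    positive_class: str | None = None
    permutation_p: float | None = None
    nodal_weights: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return len(self.truth)


def accuracy_from_counts(correct, totals) -> float:
    """Overall accuracy (%) from per-group correct/total counts."""
    correct = np.asarray(correct, dtype=float)
    totals = np.asarray(totals, dtype=float)
    return float(100.0 * correct.sum() / totals.sum())


def binary_accuracy(
    sensitivity_pct: float, specificity_pct: float, n_pos: int, n_neg: int
) -> float:
    """Accuracy (%) implied by sensitivity/specificity and group sizes."""
    return float(
        (sensitivity_pct * n_pos + specificity_pct * n_neg) / (n_pos + n_neg)
    )


def _positive_class(classes: list[str]) -> str:
    ranked = sorted(classes, key=lambda c: _SEVERITY.get(c, -1))
    return ranked[-1]


def loocv(
    X: np.ndarray,
    y: np.ndarray,
    C_reg: float = 1.0,
    standardize: bool = True,
    subject_ids: list[str] | None = None,
    positive_class: str | None = None,
) -> ClassificationReport:
    """Leave-one-out cross-validated one-vs-rest classification.

    Each subject is held out in turn; the remaining subjects train the
    classifiers (including the standardization statistics).  For binary
    problems sensitivity is the correct fraction of the positive (more
    impaired) class and specificity that of the other class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray([str(v) for v in y], dtype=object)
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("LOOCV needs at least 2 classes")
    ids = subject_ids or [f"s{i}" for i in range(n)]
    preds = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = train_ovr(
            X[mask], y[mask], C_reg=C_reg, standardize=standardize, classes=classes
        )
        scores = model.decision_scores(X[i])
        preds.append(classes[decode(scores)])
    preds_arr = np.asarray(preds, dtype=object)
    correct = preds_arr == y
    per_class = {
        cls: (int(np.sum(correct & (y == cls))), int(np.sum(y == cls)))
        for cls in classes
    }
    report = ClassificationReport(
        subjects=list(ids),
        truth=y.tolist(),
        predictions=preds_arr.tolist(),
        classes=classes,
        accuracy_pct=float(100.0 * correct.mean()),
        per_class=per_class,
    )
    if len(classes) == 2:
        pos = positive_class or _positive_class(classes)
        neg = [c for c in classes if c != pos][0]
        cp, tp = per_class[pos]
        cn, tn = per_class[neg]
        report.positive_class = pos
        report.sensitivity_pct = float(100.0 * cp / tp)
        report.specificity_pct = float(100.0 * cn / tn)
    return report


def pvalue_from_null(null_accuracies, actual: float, n_perm: int | None = None) -> float:
    """Proportion of null accuracies >= the actual accuracy."""
    null = np.asarray(null_accuracies, dtype=float)
    denom = n_perm if n_perm is not None else null.size
    return float(np.sum(null >= actual) / denom)


def permutation_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    C_reg: float = 1.0,
    standardize: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Permutation significance of the LOOCV accuracy.

    Labels are permuted once per iteration and the full LOOCV re-run;
    p is the literal proportion of null accuracies >= the actual one.
    Returns (p, actual accuracy %, null accuracies %).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    actual = loocv(X, y, C_reg=C_reg, standardize=standardize).accuracy_pct
    null = np.empty(n_perm)
    y = np.asarray([str(v) for v in y], dtype=object)
    for b in range(n_perm):
        rng = np.random.default_rng(derive_seed(seed, "perm", b))
        null[b] = loocv(
            X, y[rng.permutation(y.size)], C_reg=C_reg, standardize=standardize
        ).accuracy_pct
    return pvalue_from_null(null, actual), actual, null


def nodal_weight_map(
    model: OvrModel,
    feature_index: list[tuple[str, int, str]],
    mode: str = "sum-then-abs",
) -> dict[int, float]:
    """Per-node contribution map from the SVM hyperplane weights.

    Default ``sum-then-abs``: the signed weights of a node's three
    metric features are summed across the classifiers, then the absolute
    value is taken.  ``abs-then-sum`` sums |w| instead (the alternative
    reading of the same recipe).
    """
    if mode not in ("sum-then-abs", "abs-then-sum"):
        raise ValueError(f"unknown mode {mode!r}")
    coefs = model.coefs()
    if coefs.shape[1] != len(feature_index):
        raise ValueError("feature index does not match classifier weights")
    nodes = sorted({node for _, node, _ in feature_index})
    out = {}
    for node in nodes:
        cols = [k for k, (_, n, _) in enumerate(feature_index) if n == node]
        block = coefs[:, cols]
        if mode == "sum-then-abs":
            out[node] = float(abs(block.sum()))
        else:
            out[node] = float(np.abs(block).sum())
    return out
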