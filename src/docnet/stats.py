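"""Group-level statistics.

Two-way fixed-effects ANOVA (conscious state x brain network, with
interaction) on network-level metrics, Tukey HSD post-hoc contrasts,
baseline-referenced Pearson correlations with Bonferroni correction, and
a label-permutation test on nodal average F-values with Benjamini-
Hochberg FDR across nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, tukey_hsd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from ._seeds import derive_seed
from .errors import UnstableResolutionWarning


@dataclass
class AnovaResult:
    """One ANOVA effect: F, (df_num, df_den), p."""

    effect: str
    f: float
    df: tuple[int, int]
    p: float


def two_way_anova(table: pd.DataFrame) -> dict[str, AnovaResult]:
    """State x network fixed-effects ANOVA with interaction.

    ``table`` must hold one row per (subject, network) with columns
    ``subject``, ``state``, ``network`` and ``value``.  With 29 subjects
    and 10 networks the error df is 290 - 30 = 260 and the effect dfs
    are 2 (state), 9 (network) and 18 (interaction).
    """
    required = {"subject", "state", "network", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = table.groupby(["subject", "network"], observed=True).size()
    if (counts != 1).any():
        raise ValueError("every subject needs exactly one value per network")
    cell = table.groupby(["state", "network"], observed=True).size().unstack()
    if cell.isna().any().any():
        raise ValueError("empty state x network cell")
    model = ols("value ~ C(state) * C(network)", data=table).fit()
    aov = anova_lm(model, typ=2)
    df_err = int(aov.loc["Residual", "df"])
    degenerate = float(np.var(table["value"].to_numpy())) == 0.0
    mapping = {
        "C(state)": "state",
        "C(network)": "network",
        "C(state):C(network)": "state:network",
    }
    out = {}
    for row, name in mapping.items():
        f = 0.0 if degenerate else float(aov.loc[row, "F"])
        p = 1.0 if degenerate else float(aov.loc[row, "PR(>F)"])
        out[name] = AnovaResult(
            effect=name, f=f, df=(int(aov.loc[row, "df"]), df_err), p=p
        )
    return out


def tukey_posthoc(
    values: np.ndarray, groups: list[str]
) -> dict[tuple[str, str], tuple[float, float]]:
    """Studentized-range-adjusted pairwise contrasts.

    Returns {(a, b): (mean_a - mean_b, adjusted p)} for every group pair.
    """
    values = np.asarray(values, dtype=float)
    groups = [str(g) for g in groups]
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    samples = [values[[i for i, g in enumerate(groups) if g == n]] for n in names]
    if any(s.size < 2 for s in samples):
        raise ValueError("every group needs at least two observations")
    res = tukey_hsd(*samples)
    out = {}
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            diff = float(np.mean(samples[a]) - np.mean(samples[b]))
            out[(names[a], names[b])] = (diff, float(res.pvalue[a, b]))
    return out


def baseline_correlation(
    patient_a: np.ndarray,
    patient_b: np.ndarray,
    control_mean_a: float,
    control_mean_b: float,
    m_comparisons: int = 1,
) -> tuple[float, float, float]:
    """Pearson correlation of control-referenced patient deviations.

    Correlates per-patient (A - control mean A) against (B - control
    mean B); the Bonferroni p multiplies the raw p by ``m_comparisons``
    and caps at 1.
    """
    a = np.asarray(patient_a, dtype=float) - float(control_mean_a)
    b = np.asarray(patient_b, dtype=float) - float(control_mean_b)
    if a.size != b.size or a.size < 3:
        raise ValueError("need >= 3 paired patient values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = pearsonr(a, b)
    return float(r), float(p), float(min(1.0, p * m_comparisons))


def _group_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorized one-way ANOVA F along axis 0 (subjects) for each column."""
    n = values.shape[0]
    grand = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1:])
    ss_within = np.zeros(values.shape[1:])
    for g in range(n_groups):
        rows = values[codes == g]
        mean_g = rows.mean(axis=0)
        ss_between += rows.shape[0] * (mean_g - grand) ** 2
        ss_within += ((rows - mean_g) ** 2).sum(axis=0)
    df_b = n_groups - 1
    df_w = n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / np.where(ss_within > 0, ss_within / df_w, np.nan)
    return np.nan_to_num(f, nan=0.0, posinf=np.inf)


@dataclass
class NodalTestResult:
    """Permutation test of per-node average F across the three metrics."""

    node_id: np.ndarray
    f_avg: np.ndarray
    p: np.ndarray
    q: np.ndarray


def nodal_permutation_test(
    data: np.ndarray,
    groups: list[str],
    node_ids: np.ndarray | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> NodalTestResult:
    """Label-permutation test on nodal average F-values with BH-FDR.

    ``data`` is subjects x nodes x metrics.  The observed statistic per
    node is the average one-way ANOVA F across metrics; the null
    re-samples subjects into groups of the same sizes ``n_perm`` times.
    p is the proportion of null statistics >= the observed one; q is the
    Benjamini-Hochberg adjusted value across nodes.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be subjects x nodes x metrics")
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} gives unstable p resolution", UnstableResolutionWarning
        )
    groups = [str(g) for g in groups]
    names = sorted(set(groups))
    if len(names) < 3:
        raise ValueError("nodal permutation test expects three groups")
    codes = np.asarray([names.index(g) for g in groups])
    obs = _group_f(data, codes, len(names)).mean(axis=1)
    exceed = np.zeros_like(obs)
    for b in range(n_perm):
        rng = np.random.default_rng(derive_seed(seed, "nodal-perm", b))
        perm = rng.permutation(codes)
        null = _group_f(data, perm, len(names)).mean(axis=1)
        exceed += null >= obs
    p = exceed / n_perm
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return NodalTestResult(
        node_id=(
            np.asarray(node_ids) if node_ids is not None else np.arange(obs.size)
        ),
        f_avg=obs,
        p=p,
        q=q,
    )
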