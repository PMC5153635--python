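"""Nodal time series -> Fisher-z functional connectivity.

The preprocessing chain applied to each subject's nodes x timepoints
matrix is: linear detrending, zero-phase Chebyshev band-pass filtering
(0.01-0.08 Hz at TR = 2 s), nuisance regression (global, white-matter and
CSF signals, their first-order backward-difference derivatives, and six
motion channels, jointly in one OLS fit), and finally pairwise Pearson
correlation with Fisher's z transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    CollinearityError,
    DegenerateNodeError,
    InsufficientSamplesError,
    InvalidBandError,
)

#: |r| is clamped at 1 - Z_CLAMP before atanh so duplicated rows map to a
#: large finite z (~17.6) instead of infinity.
Z_CLAMP = 1e-15


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix with zero diagonal."""

    z: np.ndarray
    subject_id: str | None = None
    group: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def validate(self) -> None:
        z = self.z
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.all(np.isfinite(z)):
            raise ValueError("connectivity matrix contains non-finite values")
        if np.max(np.abs(z - z.T)) != 0.0:
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.any(np.diag(z) != 0.0):
            raise ValueError("connectivity diagonal must be zero")


def detrend(ts: np.ndarray) -> np.ndarray:
    """Remove the per-row least-squares line (intercept + slope).

    The residual of each row is orthogonal to both the constant and the
    linear ramp regressor.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[None, :]
    if ts.shape[1] < 3:
        raise InsufficientSamplesError(
            f"detrending needs at least 3 timepoints, got {ts.shape[1]}"
        )
    return signal.detrend(ts, axis=1, type="linear")


def bandpass(
    ts: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    tr_s: float = 2.0,
    order: int = 4,
    ripple_db: float = 0.5,
) -> np.ndarray:
    """Zero-phase Chebyshev type-I band-pass filter applied per row.

    The filter is run forward and backward (``sosfiltfilt``) so that the
    passband is phase neutral; ``order`` and ``ripple_db`` describe the
    single-pass prototype.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim == 1:
        ts = ts[None, :]
    fs = 1.0 / tr_s
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise InvalidBandError(
            f"band ({low_hz}, {high_hz}) Hz outside (0, Nyquist={nyq}) Hz"
        )
    sos = signal.cheby1(
        order, ripple_db, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
    )
    return signal.sosfiltfilt(sos, ts, axis=1)


def _derivative(rows: np.ndarray) -> np.ndarray:
    # backward difference, first element zero
    out = np.zeros_like(rows)
    out[:, 1:] = rows[:, 1:] - rows[:, :-1]
    return out


def regress_confounds(
    ts: np.ndarray,
    confounds: np.ndarray,
    add_derivatives: bool = True,
    derivative_rows: tuple[int, ...] = (0, 1, 2),
) -> np.ndarray:
    """OLS residuals of each nodal series against the confound design.

    The design matrix contains an intercept, every confound channel and
    (when ``add_derivatives``) the backward-difference derivatives of the
    rows in ``derivative_rows`` — by convention the global, white-matter
    and CSF channels.  Residuals are orthogonal to every design column.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
    if confounds.shape[1] != ts.shape[1]:
        raise ValueError(
            f"confound length {confounds.shape[1]} != series length {ts.shape[1]}"
        )
    names = [f"confound[{i}]" for i in range(confounds.shape[0])]
    blocks = [confounds]
    if add_derivatives and len(derivative_rows) > 0:
        rows = [r for r in derivative_rows if r < confounds.shape[0]]
        blocks.append(_derivative(confounds[rows]))
        names += [f"d/dt confound[{r}]" for r in rows]
    design = np.column_stack(
        [np.ones(ts.shape[1])] + [b.T for b in blocks]
    )
    names = ["intercept"] + names
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        offenders = _collinear_columns(design, names)
        raise CollinearityError(
            "confound design is rank deficient; offending channels: "
            + ", ".join(offenders)
        )
    beta, *_ = np.linalg.lstsq(design, ts.T, rcond=None)
    return ts - (design @ beta).T


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan: name columns already spanned by their predecessors."""
    offenders = []
    kept = np.empty((design.shape[0], 0))
    for j in range(design.shape[1]):
        col = design[:, j : j + 1]
        if kept.shape[1]:
            beta, *_ = np.linalg.lstsq(kept, col, rcond=None)
            resid = col - kept @ beta
        else:
            resid = col
        if np.linalg.norm(resid) < 1e-10 * max(1.0, np.linalg.norm(col)):
            offenders.append(names[j])
        else:
            kept = np.hstack([kept, col])
    return offenders


def connectivity_matrix(
    ts: np.ndarray,
    subject_id: str | None = None,
    group: str | None = None,
) -> ConnectivityMatrix:
    """Pairwise Pearson correlation, Fisher-z transformed.

    ``z_ij = atanh(r_ij)`` with |r| clamped at ``1 - Z_CLAMP``; the
    diagonal is fixed at zero.
    """
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise DegenerateNodeError(
            f"zero-variance nodal series: nodes {dead.tolist()}"
        )
    r = np.corrcoef(ts)
    r = np.clip(r, -1.0 + Z_CLAMP, 1.0 - Z_CLAMP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z=z, subject_id=subject_id, group=group)


def preprocess(
    ts: np.ndarray,
    confounds: np.ndarray | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    tr_s: float = 2.0,
    add_derivatives: bool = True,
) -> np.ndarray:
    """Full nodal preprocessing: detrend -> band-pass -> confound regression."""
    out = bandpass(detrend(ts), low_hz=low_hz, high_hz=high_hz, tr_s=tr_s)
    if confounds is not None and confounds.size:
        out = regress_confounds(out, confounds, add_derivatives=add_derivatives)
    return out


def subject_connectivity(
    record,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    tr_s: float = 2.0,
) -> ConnectivityMatrix:
    """Preprocess one subject record and return its Fisher-z matrix."""
    clean = preprocess(
        record.timeseries,
        record.confounds,
        low_hz=low_hz,
        high_hz=high_hz,
        tr_s=tr_s,
    )
    return connectivity_matrix(
        clean, subject_id=record.subject_id, group=str(record.group)
    )
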