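"""From residual time series to condition-specific thresholded graphs.

The per-condition pipeline is: regress confounds (and, for task runs, the
hemodynamically convolved event regressors) out of the node x time series;
for task events, concatenate the residual volumes belonging to the event
windows (shifted by the hemodynamic lag); correlate nodes (Pearson ->
Fisher z'); and keep the strongest edges at a set of proportional density
thresholds, binarised.

Notes on conventions: the global mean signal is never used as a regressor;
proportional thresholding ranks *signed* z values so strong negative
correlations are excluded; ties at the cutoff are broken by lexicographic
node-pair order so a run is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .synthetic import SubjectConditionSeries, TASK_CONDITIONS, hrf_regressor

logger = logging.getLogger(__name__)

DEFAULT_DENSITIES = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
DEFAULT_LAG_VOLUMES = 2
Z_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric node x node Fisher-z matrix for one subject x condition.

    The diagonal is undefined and stored as 0. ``flagged_nodes`` lists nodes
    whose variance was (numerically) zero, whose rows are NaN.
    """

    subject_id: str
    condition: str
    values: np.ndarray
    flagged_nodes: tuple = ()

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        ok = ~np.isnan(v)
        if not np.allclose(np.where(ok & ok.T, v, 0.0),
                           np.where(ok & ok.T, v.T, 0.0), atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")


@dataclass
class ThresholdedGraph:
    """Binary undirected graph at a proportional density threshold."""

    adjacency: np.ndarray
    density: float
    subject_id: str | None = None
    condition: str | None = None

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


# ---------------------------------------------------------------------------
# confound regression
# ---------------------------------------------------------------------------


def regress_confounds(data: np.ndarray, confounds: np.ndarray | None = None,
                      task_regressors: np.ndarray | None = None,
                      rank_tol: float = 1e-10) -> np.ndarray:
    """OLS-residualise every node's series against intercept + regressors.

    Collinear regressor columns are dropped (with a warning) via
    rank-revealing QR before solving; residuals are orthogonal to every
    retained regressor. More regressors than time points is a hard error.
    """
    Y = np.asarray(data, float)
    T = Y.shape[1]
    parts = [np.ones((T, 1))]
    if confounds is not None and np.size(confounds):
        parts.append(np.asarray(confounds, float).T)
    if task_regressors is not None and np.size(task_regressors):
        tr = np.asarray(task_regressors, float)
        parts.append(tr[:, None] if tr.ndim == 1 else tr.T)
    X = np.hstack(parts)
    if X.shape[1] >= T:
        raise ValueError(f"{X.shape[1]} regressors for {T} time points")
    # drop collinear columns, keeping earlier ones
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > rank_tol * max(diag[0], 1.0)).sum())
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        logger.warning("dropping %d collinear regressor column(s)",
                       X.shape[1] - rank)
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = (Y.T - X @ beta).T
    degenerate = np.flatnonzero(resid.std(axis=1) < 1e-12)
    if degenerate.size:
        logger.warning("%d node(s) constant after residualisation: %s",
                       degenerate.size, degenerate.tolist())
    return resid


# ---------------------------------------------------------------------------
# event-window extraction
# ---------------------------------------------------------------------------


def extract_event_series(data: np.ndarray, events: pd.DataFrame, event_type: str,
                         lag_volumes: int = DEFAULT_LAG_VOLUMES,
                         repetition_time: float = 2.0) -> np.ndarray:
    """Concatenate the residual volumes belonging to one event type.

    For each event row matching ``event_type``, the volumes in
    ``[onset + lag, onset + lag + duration)`` (rounded to the volume grid,
    at least one volume per event) are taken in trial order. Overlapping
    windows keep their volumes per event (duplication allowed); windows
    running past the end of the run are truncated and logged.
    """
    if lag_volumes < 0:
        raise ValueError("lag_volumes must be >= 0")
    sel = events[events["event_type"] == event_type]
    if len(sel) == 0:
        raise ValueError(f"no events of type {event_type!r} in the event table")
    T = data.shape[1]
    cols: list[np.ndarray] = []
    truncated = 0
    for _, row in sel.iterrows():
        start = int(np.floor(row["onset"] / repetition_time)) + lag_volumes
        n_vol = max(1, int(np.round(row["duration"] / repetition_time)))
        stop = start + n_vol
        if stop > T:
            truncated += 1
            stop = T
        if start < T:
            cols.append(np.arange(start, stop))
    if truncated:
        logger.warning("%d %s event window(s) truncated at the run end",
                       truncated, event_type)
    idx = np.concatenate(cols)
    return data[:, idx]


# ---------------------------------------------------------------------------
# connectivity and thresholding
# ---------------------------------------------------------------------------


def compute_connectivity(data: np.ndarray, subject_id: str = "",
                         condition: str = "") -> ConnectivityMatrix:
    """Fisher z' of the Pearson correlation matrix of a node x time series.

    r is clipped to |r| <= 1 - 1e-7 before atanh so entries stay finite;
    zero-variance nodes yield NaN rows and are flagged.
    """
    X = np.asarray(data, float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 time points for a correlation")
    sd = X.std(axis=1)
    flagged = tuple(np.flatnonzero(sd < 1e-12).tolist())
    if flagged:
        logger.warning("zero-variance node(s) %s: connectivity undefined", flagged)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    z = np.arctanh(np.clip(r, -Z_CLIP, Z_CLIP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(subject_id, condition, z, flagged)


def threshold_proportional(matrix, density: float) -> ThresholdedGraph:
    """Keep the top ``k = round(density * n(n-1)/2)`` edges, binarised.

    Edges are ranked by signed value, largest first; exact ties at the cutoff
    are resolved in lexicographic (i, j) node-pair order.
    """
    if isinstance(matrix, ConnectivityMatrix):
        values, sid, cond = matrix.values, matrix.subject_id, matrix.condition
    else:
        values, sid, cond = np.asarray(matrix, float), None, None
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = values[iu, ju]
    if np.isnan(w).any():
        w = np.where(np.isnan(w), -np.inf, w)
    k = int(round(density * n * (n - 1) / 2))
    if k == 0:
        raise ValueError(f"density {density} keeps zero edges on {n} nodes")
    order = np.lexsort((ju, iu, -w))   # value desc, then (i, j) lexicographic
    keep = order[:k]
    A = np.zeros((n, n))
    A[iu[keep], ju[keep]] = 1.0
    A += A.T
    return ThresholdedGraph(A, density, sid, cond)


# ---------------------------------------------------------------------------
# per-series pipeline
# ---------------------------------------------------------------------------


def subject_connectivity(series: SubjectConditionSeries,
                         lag_volumes: int = DEFAULT_LAG_VOLUMES) -> ConnectivityMatrix:
    """Full residualise -> (extract) -> correlate pipeline for one series.

    Task conditions regress out the convolved regressor of every task event
    type present in the event table, then concatenate the windows of the
    series' own condition; resting conditions only regress confounds.
    """
    if series.condition in TASK_CONDITIONS:
        if series.events is None:
            raise ValueError(f"{series.condition} series carries no event table")
        T = series.data.shape[1]
        regs = []
        for etype in TASK_CONDITIONS:
            ev = series.events[series.events["event_type"] == etype]
            if len(ev):
                regs.append(hrf_regressor(ev, T, series.repetition_time))
        resid = regress_confounds(series.data, series.confounds,
                                  np.stack(regs) if regs else None)
        data = extract_event_series(resid, series.events, series.condition,
                                    lag_volumes, series.repetition_time)
    else:
        data = regress_confounds(series.data, series.confounds)
    return compute_connectivity(data, series.subject_id, series.condition)


def cohort_connectivity(series_list, lag_volumes: int = DEFAULT_LAG_VOLUMES):
    """Connectivity matrices for every series, keyed (subject, condition)."""
    return {(s.subject_id, s.condition): subject_connectivity(s, lag_volumes)
            for s in series_list}
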