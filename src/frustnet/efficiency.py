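"""Module global efficiency and the held-out prediction framework.

Global efficiency of a module — the mean inverse shortest-path length over
node pairs of the subgraph induced by the module's members, with disconnected
pairs contributing 0 — indexes the module's capacity for parallel information
transfer. The prediction framework mirrors a conservative
train/validation/held-out protocol:

1. stratified split of the cohort on the outcome (48/18 by default);
2. standardize every column using training statistics only;
3. forward/backward stepwise selection scored by repeated k-fold
   cross-validated RMSE on the training set (10 folds x 20 repeats);
4. refit on the full training set, predict the held-out subjects, and test
   the held-out Pearson r with a one-sided permutation test;
5. Benjamini-Hochberg FDR across the family of primary outcome models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from sklearn.model_selection import RepeatedKFold, train_test_split
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# global efficiency
# ---------------------------------------------------------------------------


def global_efficiency(graph, node_subset=None) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Computed on the subgraph induced by ``node_subset`` (all nodes if None)
    with unweighted BFS distances; ``1/inf = 0`` for disconnected pairs, so
    the value lies in [0, 1] with 1 for a complete (sub)graph.
    """
    A = np.asarray(getattr(graph, "adjacency", graph), float)
    if node_subset is not None:
        idx = np.asarray(node_subset)
        A = A[np.ix_(idx, idx)]
    n = A.shape[0]
    if n < 2:
        raise ValueError("node subset must have at least 2 nodes")
    D = shortest_path(A, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / D
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def build_efficiency_table(graphs: dict, consensus_partitions: dict,
                           covariates: pd.DataFrame | None = None,
                           min_module_size: int = 4) -> pd.DataFrame:
    """Subjects x (condition:module E_glob, covariates) predictor table.

    ``graphs`` maps (subject, condition) to the subject's thresholded graph
    at the analysis density; ``consensus_partitions`` maps condition to that
    condition's group consensus partition, whose modules (> 3 nodes) define
    the node subsets. Columns are named ``<condition>:M<module>``. A missing
    condition for any subject is an error (complete-case design).
    Zero-variance columns are dropped with a warning. No standardization
    happens here — that is fit on training subjects only, downstream.
    """
    subjects = sorted({s for s, _ in graphs})
    conditions = list(consensus_partitions)
    rows = {}
    for sid in subjects:
        row = {}
        for cond in conditions:
            if (sid, cond) not in graphs:
                raise ValueError(f"subject {sid} is missing condition {cond}")
            g = graphs[(sid, cond)]
            part = consensus_partitions[cond]
            part = part.partition if hasattr(part, "partition") else part
            for m in sorted(part.large_modules(min_module_size)):
                row[f"{cond}:M{m}"] = global_efficiency(g, part.members(m))
        rows[sid] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "subject"
    if covariates is not None:
        table = table.join(covariates.loc[table.index])
    dead = [c for c in table.columns if table[c].std() == 0]
    if dead:
        logger.warning("dropping zero-variance column(s): %s", dead)
        table = table.drop(columns=dead)
    return table


# ---------------------------------------------------------------------------
# split / stepwise selection / evaluation
# ---------------------------------------------------------------------------


@dataclass
class SplitRecord:
    train_ids: list
    test_ids: list
    stratify_on: str
    n_bins: int
    seed: int


def stratified_split(phenotypes: pd.DataFrame, outcome: str, train_n: int = 48,
                     test_n: int = 18, seed: int = 0, n_bins: int = 4) -> SplitRecord:
    """Deterministic stratified train/held-out split on outcome quantile bins.

    Falls back to fewer bins (logged) when quantile bins are too small or
    degenerate; a constant outcome yields an unstratified split with a
    warning.
    """
    y = phenotypes[outcome]
    if train_n + test_n != len(y):
        raise ValueError(f"train_n + test_n = {train_n + test_n} != cohort size {len(y)}")
    rs = int(np.random.SeedSequence([seed, 0x51A7]).generate_state(1)[0] % (2 ** 31))
    bins = None
    used_bins = n_bins
    while used_bins >= 2:
        try:
            cand = pd.qcut(y, q=used_bins, labels=False, duplicates="drop")
        except ValueError:
            cand = None
        if (cand is not None and 2 <= cand.nunique() <= min(train_n, test_n)
                and cand.value_counts().min() >= 2):
            bins = cand
            break
        used_bins -= 1
    if bins is None:
        logger.warning("outcome %s not stratifiable; using an unstratified split", outcome)
        used_bins = 1
    if used_bins < n_bins and bins is not None:
        logger.info("outcome %s stratified on %d bins", outcome, used_bins)
    tr, te = train_test_split(np.asarray(y.index), train_size=train_n,
                              test_size=test_n, random_state=rs,
                              stratify=None if bins is None else bins)
    return SplitRecord(sorted(tr.tolist()), sorted(te.tolist()), outcome, used_bins, seed)


@dataclass
class StepwiseModel:
    """Linear model selected by stepwise search under CV-RMSE."""

    predictors: list
    coef: np.ndarray          # aligned with predictors
    intercept: float
    cv_rmse: float
    search_trace: list = field(default_factory=list)

    @property
    def is_intercept_only(self) -> bool:
        return len(self.predictors) == 0

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.is_intercept_only:
            return np.full(len(X), self.intercept)
        return self.intercept + X[self.predictors].to_numpy() @ self.coef


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xd = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return beta


def _cv_rmse(X: np.ndarray, y: np.ndarray, cols: list, folds) -> float:
    sq = 0.0
    n = 0
    Xc = X[:, cols] if cols else np.empty((len(y), 0))
    for tr, te in folds:
        beta = _ols(Xc[tr], y[tr])
        pred = beta[0] + (Xc[te] @ beta[1:] if cols else 0.0)
        sq += float(((y[te] - pred) ** 2).sum())
        n += len(te)
    return np.sqrt(sq / n)


def stepwise_cv_select(train: pd.DataFrame, y: pd.Series | np.ndarray,
                       k: int = 10, repeats: int = 20, seed: int = 0,
                       max_predictors: int | None = None,
                       tol: float = 1e-9) -> StepwiseModel:
    """Forward/backward stepwise regression scored by repeated k-fold CV RMSE.

    From the empty model, the best single addition (and, after each addition,
    any beneficial deletion) is applied while it lowers the mean
    cross-validated RMSE; the visited model with the lowest CV RMSE wins and
    is refit on the full training set. The same fold set is reused for every
    candidate so comparisons are paired. An intercept-only winner signals
    that no predictor beats the mean.
    """
    X = train.to_numpy(float)
    y = np.asarray(y, float)
    n, p = X.shape
    if max_predictors is None:
        max_predictors = max(1, min(p, n // 3))
    rs = int(np.random.SeedSequence([seed, 0x57E9]).generate_state(1)[0] % (2 ** 31))
    k_eff = min(k, n)
    if k_eff < k:
        logger.info("reducing CV folds from %d to %d for n=%d", k, k_eff, n)
    folds = list(RepeatedKFold(n_splits=k_eff, n_repeats=repeats,
                               random_state=rs).split(X))
    names = list(train.columns)
    current: list[int] = []
    best_rmse = _cv_rmse(X, y, current, folds)
    best_overall = (best_rmse, [])
    trace = [(0, best_rmse)]
    improved = True
    while improved and len(current) < max_predictors:
        improved = False
        candidates = [j for j in range(p) if j not in current]
        scores = [( _cv_rmse(X, y, current + [j], folds), j) for j in candidates]
        if not scores:
            break
        rmse_add, j_add = min(scores)
        if rmse_add < best_rmse - tol:
            current.append(j_add)
            best_rmse = rmse_add
            improved = True
            # backward sweep
            changed = True
            while changed and len(current) > 1:
                changed = False
                for j in list(current):
                    trial = [c for c in current if c != j]
                    rm = _cv_rmse(X, y, trial, folds)
                    if rm < best_rmse - tol:
                        current = trial
                        best_rmse = rm
                        changed = True
            trace.append((len(current), best_rmse))
            if best_rmse < best_overall[0] - tol:
                best_overall = (best_rmse, list(current))
    rmse, chosen = best_overall
    beta = _ols(X[:, chosen] if chosen else np.empty((n, 0)), y)
    return StepwiseModel([names[j] for j in chosen], beta[1:], float(beta[0]),
                         rmse, trace)


@dataclass
class PredictionResult:
    """Held-out evaluation of one outcome's selected model."""

    outcome: str
    predictors: list
    coef: np.ndarray
    r: float
    r2: float
    rmse: float
    p: float
    q: float | None
    n_perm: int
    split: SplitRecord | None = None
    failed: bool = False

    def to_dict(self) -> dict:
        return {"outcome": self.outcome,
                "predictors": ";".join(self.predictors),
                "r": self.r, "r2": self.r2, "rmse": self.rmse,
                "p_perm": self.p, "q_fdr": self.q, "failed": self.failed}


def evaluate_heldout(model: StepwiseModel, test: pd.DataFrame, y_test,
                     outcome: str = "", n_perm: int = 5000, seed: int = 0,
                     split: SplitRecord | None = None) -> PredictionResult:
    """Held-out Pearson r / R^2 / RMSE with a one-sided permutation p on r > 0.

    The permutation null shuffles the held-out outcome values. An
    intercept-only model has no defined r and is recorded as a failure with
    p = 1.
    """
    y = np.asarray(y_test, float)
    if model.is_intercept_only:
        return PredictionResult(outcome, [], np.empty(0), np.nan, np.nan,
                                float(np.sqrt(((y - model.intercept) ** 2).mean())),
                                1.0, None, n_perm, split, failed=True)
    pred = model.predict(test)
    r_obs = float(np.corrcoef(pred, y)[0, 1])
    rmse = float(np.sqrt(((y - pred) ** 2).mean()))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE7A1]))
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    pc = (pred - pred.mean()) / pred.std()
    yc = (perms - perms.mean(axis=1, keepdims=True)) / perms.std(axis=1, keepdims=True)
    r_perm = yc @ pc / len(y)
    p = float((1.0 + (r_perm >= r_obs - 1e-12).sum()) / (n_perm + 1.0))
    return PredictionResult(outcome, model.predictors, model.coef, r_obs,
                            r_obs ** 2, rmse, p, None, n_perm, split)


def fdr_correct(results: list[PredictionResult]) -> list[PredictionResult]:
    """Benjamini-Hochberg q-values across a family of outcome models."""
    if not results:
        return results
    ps = np.array([r.p for r in results])
    _, qs, _, _ = multipletests(ps, method="fdr_bh")
    for r, q in zip(results, qs):
        r.q = float(max(q, r.p))
    return results


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _standardize(train: pd.DataFrame, test: pd.DataFrame):
    mu, sd = train.mean(), train.std().replace(0.0, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def run_prediction(table: pd.DataFrame, phenotypes: pd.DataFrame, outcome: str,
                   train_n: int = 48, test_n: int = 18, k: int = 10,
                   repeats: int = 20, n_perm: int = 5000, seed: int = 0,
                   leak_selection: bool = False) -> PredictionResult:
    """Split -> standardize (train stats) -> stepwise CV -> held-out test.

    ``leak_selection=True`` deliberately fits standardization and selection on
    the full sample before "held-out" evaluation; it exists only as a
    negative control demonstrating the optimism such leakage produces.
    """
    split = stratified_split(phenotypes, outcome, train_n, test_n, seed)
    Xtr, Xte = table.loc[split.train_ids], table.loc[split.test_ids]
    ytr = phenotypes.loc[split.train_ids, outcome]
    yte = phenotypes.loc[split.test_ids, outcome]
    if leak_selection:
        Xall, _ = _standardize(table, table)
        yall = (phenotypes[outcome] - phenotypes[outcome].mean()) / phenotypes[outcome].std()
        model = stepwise_cv_select(Xall, yall, k=k, repeats=repeats, seed=seed)
        Xte_s = Xall.loc[split.test_ids]
        yte_s = yall.loc[split.test_ids]
    else:
        Xtr_s, Xte_s = _standardize(Xtr, Xte)
        mu, sd = ytr.mean(), ytr.std() or 1.0
        ytr_s, yte_s = (ytr - mu) / sd, (yte - mu) / sd
        model = stepwise_cv_select(Xtr_s, ytr_s, k=k, repeats=repeats, seed=seed)
    res = evaluate_heldout(model, Xte_s, yte_s, outcome, n_perm, seed, split)
    return res


def run_prediction_family(table: pd.DataFrame, phenotypes: pd.DataFrame,
                          primary_outcomes, null_outcomes=(), **kwargs
                          ) -> dict[str, PredictionResult]:
    """All outcome models; BH-FDR across the primary family only.

    Specificity (null) outcomes are reported with uncorrected p, mirroring
    the convention of reporting specificity models without correction.
    """
    primary = [run_prediction(table, phenotypes, o, **kwargs) for o in primary_outcomes]
    fdr_correct(primary)
    nulls = [run_prediction(table, phenotypes, o, **kwargs) for o in null_outcomes]
    return {r.outcome: r for r in primary + nulls}
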