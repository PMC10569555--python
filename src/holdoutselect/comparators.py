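"""Baseline selection strategies run inside the identical hold-out framework.

Three comparator methods mirror common practice: keeping the univariately
significant predictors, greedy forward selection under an information
criterion, and an L1-penalised (lasso) fit with the penalty chosen by
average test performance over the shared splits.  All comparators consume
the same SplitPlan as the main engine, so differences in predictive power
are attributable to the selection strategy alone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LogisticRegression

from . import estimators, metrics
from .data_model import OutcomeSpec, PredictorTable
from .holdout import SplitPlan

__all__ = ["ComparatorResult", "significant_model", "stepwise_forward_model",
           "l1_path_model", "run_comparator", "overfitting_measure"]


@dataclass
class ComparatorResult:
    method: str
    metric: str
    avg_test: float
    avg_train: float
    per_split_test: np.ndarray
    per_split_train: np.ndarray
    per_split_support: list  # 1-based index tuples
    lambda_grid: np.ndarray | None = None
    chosen_lambda: float | None = None
    extras: dict = field(default_factory=dict)


def _design_parts(table: PredictorTable):
    spans, blocks, start = [], [], 0
    for j in range(table.n_columns):
        b = table.design_block(j)
        blocks.append(b)
        spans.append(list(range(start, start + b.shape[1])))
        start += b.shape[1]
    F = np.hstack(blocks) if blocks else np.empty((table.n_rows, 0))
    return F, spans


def _metric_pair(outcome: OutcomeSpec, model, Xtr, Xte, y_tr, y_te,
                 metric: str, cutoff: float):
    """(test, train) metric values for a fitted model; ``model=None`` scores
    the empirical prediction."""
    if outcome.mode == "linear":
        if model is None:
            mu = float(y_tr.mean())
            yhat_te = np.full(len(y_te), mu)
            yhat_tr = np.full(len(y_tr), mu)
        else:
            yhat_te = estimators.predict_linear(model, Xte)
            yhat_tr = estimators.predict_linear(model, Xtr)
        a_te, r_te = metrics.abs_rel_error(y_te, yhat_te)
        a_tr, r_tr = metrics.abs_rel_error(y_tr, yhat_tr)
        return (a_te, a_tr) if metric == "abs" else (r_te, r_tr)
    if model is None:
        if metric == "roc":
            return 0.5 if len(np.unique(y_te)) == 2 else float("nan"), \
                   0.5 if len(np.unique(y_tr)) == 2 else float("nan")
        return (metrics.accuracy(y_te, np.zeros(len(y_te), dtype=int)),
                metrics.accuracy(y_tr, np.zeros(len(y_tr), dtype=int)))
    p_te = estimators.categorical_probs(model, Xte)
    p_tr = estimators.categorical_probs(model, Xtr)
    if metric == "roc":
        return metrics.auroc(y_te, p_te[:, 1]), metrics.auroc(y_tr, p_tr[:, 1])
    return (metrics.accuracy(y_te, estimators.classify(p_te, outcome.mode, cutoff)),
            metrics.accuracy(y_tr, estimators.classify(p_tr, outcome.mode, cutoff)))


def _default_metric(outcome: OutcomeSpec, metric: str | None) -> str:
    if metric is not None:
        return metric
    return "abs" if outcome.mode == "linear" else "acc"


def univariate_p_value(Xb: np.ndarray, y: np.ndarray, outcome_mode: str, L: int = 0) -> float:
    """p-value of a single-predictor model against the null.

    Linear: the model-vs-null F test (equals the slope t test for one
    column).  Categorical: likelihood-ratio chi-square with d*(L-1) degrees
    of freedom.  Unfittable models return p = 1.
    """
    n, d = Xb.shape
    if outcome_mode == "linear":
        A = np.column_stack([np.ones(n), Xb])
        coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < d + 1 or n - d - 1 < 1:
            return 1.0
        resid = y - A @ coef
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        if tss <= 0 or rss <= 0:
            return 0.0 if tss > rss else 1.0
        f = ((tss - rss) / d) / (rss / (n - d - 1))
        return float(stats.f.sf(f, d, n - d - 1))
    try:
        m = estimators._fit_categorical((0,), Xb, y, outcome_mode, L)
    except estimators.FitError:
        return 1.0
    lr = 2.0 * (m.logLm - m.logL0)
    return float(stats.chi2.sf(lr, d * (L - 1)))


def significant_model(split, table: PredictorTable, outcome: OutcomeSpec,
                      alpha: float = 0.05, metric: str | None = None,
                      cutoff: float = 0.5, _parts=None):
    """Fit the model of all univariately significant predictors on one split.

    Returns ``(test_metric, train_metric, kept)`` with ``kept`` a 1-based
    index tuple; an empty kept set falls back to the empirical prediction.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    metric = _default_metric(outcome, metric)
    F, spans = _parts if _parts is not None else _design_parts(table)
    train, test = split
    y_tr, y_te = outcome.encoded[train], outcome.encoded[test]
    L = outcome.n_categories
    kept = []
    for j in range(table.n_columns):
        if table.columns[j].weight == 0:
            continue
        p = univariate_p_value(F[np.ix_(train, spans[j])], y_tr, outcome.mode, L)
        if p < alpha or alpha >= 1.0:
            kept.append(j)
    model = None
    cols = [c for j in kept for c in spans[j]]
    if kept:
        try:
            model = estimators.fit(tuple(kept), F[np.ix_(train, cols)],
                                   outcome.restrict(train))
        except estimators.FitError:
            return float("nan"), float("nan"), tuple(k + 1 for k in kept)
    te, tr = _metric_pair(outcome, model, F[np.ix_(train, cols)],
                          F[np.ix_(test, cols)], y_tr, y_te, metric, cutoff)
    return te, tr, tuple(k + 1 for k in kept)


def _ic(outcome: OutcomeSpec, Xb, y) -> float:
    """-2 logL + 2k information criterion of a fitted candidate (AIC form)."""
    n = len(y)
    if outcome.mode == "linear":
        d = Xb.shape[1]
        if d == 0:
            rss = float(((y - y.mean()) ** 2).sum())
        else:
            A = np.column_stack([np.ones(n), Xb])
            coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
            if rank < d + 1:
                return math.inf
            resid = y - A @ coef
            rss = float(resid @ resid)
        if rss <= 0:
            return -math.inf
        m2ll = n * math.log(2 * math.pi * rss / n) + n
        return m2ll + 2 * (d + 1)
    L = outcome.n_categories
    if Xb.shape[1] == 0:
        counts = np.bincount(y.astype(int), minlength=L)
        if (counts == 0).any():
            return math.inf
        logl = float(np.sum(counts[counts > 0] * np.log(counts[counts > 0] / n)))
        return -2 * logl + 2 * (L - 1)
    try:
        m = estimators._fit_categorical((0,), Xb, y, outcome.mode, L)
    except estimators.FitError:
        return math.inf
    return -2 * m.logLm + 2 * (Xb.shape[1] + 1) * (L - 1)


def stepwise_forward_model(split, table: PredictorTable, outcome: OutcomeSpec,
                           metric: str | None = None, cutoff: float = 0.5,
                           _parts=None):
    """Greedy forward selection from the empty model under -2 logL + 2k.

    Each step adds the predictor whose inclusion most reduces the criterion;
    selection stops when no addition reduces it.  Returns
    ``(test_metric, train_metric, selected)``.
    """
    metric = _default_metric(outcome, metric)
    F, spans = _parts if _parts is not None else _design_parts(table)
    train, test = split
    y_tr, y_te = outcome.encoded[train], outcome.encoded[test]
    selected: list = []
    current_cols: list = []
    best_ic = _ic(outcome, F[np.ix_(train, [])], y_tr)
    remaining = [j for j in range(table.n_columns) if table.columns[j].weight > 0]
    while remaining:
        scores = []
        for j in remaining:
            cols = current_cols + spans[j]
            scores.append((_ic(outcome, F[np.ix_(train, cols)], y_tr), j))
        ic_new, j_new = min(scores)
        if ic_new >= best_ic:
            break
        best_ic = ic_new
        selected.append(j_new)
        current_cols += spans[j_new]
        remaining.remove(j_new)
    model = None
    if selected:
        try:
            model = estimators.fit(tuple(selected), F[np.ix_(train, current_cols)],
                                   outcome.restrict(train))
        except estimators.FitError:
            return float("nan"), float("nan"), tuple(sorted(j + 1 for j in selected))
    te, tr = _metric_pair(outcome, model, F[np.ix_(train, current_cols)],
                          F[np.ix_(test, current_cols)], y_tr, y_te, metric, cutoff)
    return te, tr, tuple(sorted(j + 1 for j in selected))


def default_lambda_grid(F: np.ndarray, y: np.ndarray, mode: str,
                        n_values: int = 50, decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from lambda_max (smallest penalty zeroing every
    coefficient on the full standardised data) down by ``decades``."""
    sd = F.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (F - F.mean(axis=0)) / sd
    yc = y.astype(float) - y.astype(float).mean()
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / len(y))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * 10 ** (-decades), n_values)


def _l1_fit_predictor(Xtr, y_tr, lam, mode: str):
    """Fit one L1-penalised model; returns (predict(X)->scores/values, support mask)."""
    solver = "liblinear" if len(np.unique(y_tr)) == 2 else "saga"
    if mode == "linear":
        est = Lasso(alpha=lam, max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xtr, y_tr)
        return est, np.abs(est.coef_) > 1e-10
    est = LogisticRegression(l1_ratio=1.0, C=1.0 / (len(y_tr) * lam),
                             solver=solver, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Xtr, y_tr)
    return est, (np.abs(est.coef_) > 1e-10).any(axis=0)


def l1_path_model(split_plan: SplitPlan, table: PredictorTable, outcome: OutcomeSpec,
                  lambda_grid=None, metric: str | None = None,
                  cutoff: float = 0.5) -> ComparatorResult:
    """L1-penalised comparator over a lambda grid shared by all splits.

    For each lambda the penalised model is fitted on every training set and
    scored on the matching test set (design standardised by training
    moments); the lambda with the best average test metric is reported along
    with the per-split support sets it selects.
    """
    metric = _default_metric(outcome, metric)
    F, spans = _design_parts(table)
    y = outcome.encoded
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(F, y, outcome.mode)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    n_lam = len(lambda_grid)
    crv = split_plan.crv
    test_vals = np.full((n_lam, crv), np.nan)
    train_vals = np.full((n_lam, crv), np.nan)
    supports = [[None] * crv for _ in range(n_lam)]
    minimize = metric in ("abs", "rel")

    for s, (train, test) in enumerate(split_plan.splits):
        mu = F[train].mean(axis=0)
        sd = F[train].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (F[train] - mu) / sd
        Xte = (F[test] - mu) / sd
        y_tr, y_te = y[train], y[test]
        for li, lam in enumerate(lambda_grid):
            try:
                est, mask = _l1_fit_predictor(Xtr, y_tr, lam, outcome.mode)
            except Exception:  # noqa: BLE001 - solver failure skips the split
                continue
            if outcome.mode == "linear":
                yhat_te, yhat_tr = est.predict(Xte), est.predict(Xtr)
                a_te, r_te = metrics.abs_rel_error(y_te, yhat_te)
                a_tr, r_tr = metrics.abs_rel_error(y_tr, yhat_tr)
                te, tr = (a_te, a_tr) if metric == "abs" else (r_te, r_tr)
            else:
                p_te, p_tr = est.predict_proba(Xte), est.predict_proba(Xtr)
                if metric == "roc":
                    te = metrics.auroc(y_te, p_te[:, 1])
                    tr = metrics.auroc(y_tr, p_tr[:, 1])
                else:
                    te = metrics.accuracy(y_te, estimators.classify(p_te, outcome.mode, cutoff))
                    tr = metrics.accuracy(y_tr, estimators.classify(p_tr, outcome.mode, cutoff))
            test_vals[li, s], train_vals[li, s] = te, tr
            col_mask = np.flatnonzero(mask)
            supports[li][s] = tuple(sorted({j + 1 for j in range(table.n_columns)
                                            if set(spans[j]) & set(col_mask)}))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg_test = np.nanmean(test_vals, axis=1)
        avg_train = np.nanmean(train_vals, axis=1)
    ok = ~np.isnan(avg_test)
    if not ok.any():
        raise RuntimeError("no lambda value produced a fit on any split")
    li = int(np.nanargmin(avg_test) if minimize else np.nanargmax(avg_test))
    return ComparatorResult(
        "l1_path", metric, float(avg_test[li]), float(avg_train[li]),
        test_vals[li], train_vals[li],
        [sup if sup is not None else () for sup in supports[li]],
        lambda_grid=lambda_grid, chosen_lambda=float(lambda_grid[li]),
        extras={"avg_test_by_lambda": avg_test, "avg_train_by_lambda": avg_train})


def run_comparator(method: str, table: PredictorTable, outcome: OutcomeSpec,
                   split_plan: SplitPlan, alpha: float = 0.05,
                   metric: str | None = None, cutoff: float = 0.5,
                   lambda_grid=None) -> ComparatorResult:
    """Evaluate one comparator over every split of the shared plan."""
    if method == "l1_path":
        return l1_path_model(split_plan, table, outcome, lambda_grid, metric, cutoff)
    metric = _default_metric(outcome, metric)
    parts = _design_parts(table)
    te = np.full(split_plan.crv, np.nan)
    tr = np.full(split_plan.crv, np.nan)
    supports = []
    for s, split in enumerate(split_plan.splits):
        if method == "significant":
            te[s], tr[s], sup = significant_model(split, table, outcome, alpha,
                                                  metric, cutoff, _parts=parts)
        elif method == "stepwise_forward":
            te[s], tr[s], sup = stepwise_forward_model(split, table, outcome,
                                                       metric, cutoff, _parts=parts)
        else:
            raise ValueError(f"unknown comparator {method!r}")
        supports.append(sup)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg_te, avg_tr = float(np.nanmean(te)), float(np.nanmean(tr))
    return ComparatorResult(method, metric, avg_te, avg_tr, te, tr, supports)


def overfitting_measure(test_metric: float, train_metric: float, metric: str) -> float:
    """Relative generalisation gap of a model.

    Error metrics: ``(test - train) / test``; accuracy/AUROC:
    ``(train - test) / train``.  Zero when test and train agree; NaN when
    the denominator vanishes.
    """
    if metric in ("abs", "rel", "abs_error", "rel_error"):
        if test_metric == 0:
            return float("nan") if train_metric != test_metric else 0.0
        return (test_metric - train_metric) / test_metric
    if train_metric == 0:
        return float("nan") if train_metric != test_metric else 0.0
    return (train_metric - test_metric) / train_metric
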