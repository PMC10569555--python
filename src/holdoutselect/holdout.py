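"""The repeated hold-out engine.

For each of ``crv`` random splits the engine checks every candidate subset
against the per-split feasibility gates (EPV on the training events, then
optionally the shrinkage/R² criteria and error margins), fits the survivors
on the training rows, scores them on the test rows, and finally averages
each model's predictive power over the splits where it was evaluated.
Models are ranked by those averages; all exact ties are reported.

Determinism: each split draws its test rows from an RNG seeded by
``(seed, split_index)``, so results are bit-identical between serial and
parallel execution and independent of worker scheduling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from . import estimators, feasibility, metrics
from .data_model import Constraints, OutcomeSpec, PredictorTable
from .enumeration import enumerate_subsets

__all__ = ["SplitPlan", "RankingResult", "make_splits", "run",
           "REASON_LABELS", "evaluate_split"]

# per-split skip reasons for a candidate model
R_OK, R_EPV, R_RSQ, R_RILEY, R_MARGIN, R_FIT = 0, 1, 2, 3, 4, 5
REASON_LABELS = {R_OK: "ok", R_EPV: "epv", R_RSQ: "rsq", R_RILEY: "riley",
                 R_MARGIN: "margin", R_FIT: "fit"}


@dataclass(frozen=True)
class SplitPlan:
    """crv random train/test partitions; test size is floor(N / part)."""

    n_rows: int
    crv: int
    part: int
    seed: int
    splits: tuple  # of (train_indices, test_indices)

    def __hash__(self):
        return hash((self.n_rows, self.crv, self.part, self.seed))


def make_splits(N: int, crv: int, part: int, seed: int) -> SplitPlan:
    """Draw ``crv`` independent uniform test subsets of size floor(N/part)."""
    if part < 2 or N < part:
        raise ValueError("need N >= part >= 2")
    m = N // part
    if m < 1:
        raise ValueError("test set would be empty")
    splits = []
    for i in range(crv):
        rng = np.random.default_rng([seed, i])
        test = np.sort(rng.choice(N, size=m, replace=False))
        mask = np.ones(N, dtype=bool)
        mask[test] = False
        splits.append((np.flatnonzero(mask), test))
    return SplitPlan(N, crv, part, seed, tuple(splits))


def _training_events(y_enc: np.ndarray, mode: str, n_cat: int) -> int:
    if mode == "linear":
        return len(y_enc)
    counts = np.bincount(y_enc.astype(int), minlength=n_cat)
    return int(counts.min())


def evaluate_split(F: np.ndarray, col_spans, outcome: OutcomeSpec,
                   train: np.ndarray, test: np.ndarray, candidates,
                   constraints: Constraints, objective: str,
                   rsq_threshold=None):
    """Evaluate every candidate on one split.

    Returns ``(vals, reasons, emp)``: ``vals`` is (n_candidates, n_metrics)
    with NaN where a model was skipped (or its AUROC was undefined on a
    one-class test set), ``reasons`` the per-candidate skip codes, ``emp``
    the empirical-baseline values for this split.
    """
    mode = outcome.mode
    linear = mode == "linear"
    n_vals = 4 if linear else 2
    vals = np.full((len(candidates), n_vals), np.nan)
    reasons = np.zeros(len(candidates), dtype=np.int8)

    Ftr, Fte = F[train], F[test]
    y_tr = outcome.restrict(train)
    y_te_enc = outcome.encoded[test]
    n_tr = len(train)
    events = _training_events(y_tr.encoded, mode, outcome.n_categories)

    # binary proportion margin is model-independent
    margin_blocked = False
    if constraints.marg is not None and mode in ("binary", "multin"):
        mb = feasibility.proportion_margin(events / n_tr, n_tr)
        margin_blocked = mb > constraints.marg

    for ci, sub in enumerate(candidates):
        if not feasibility.epv_feasible(sub.weight, events, constraints.epv_rule):
            reasons[ci] = R_EPV
            continue
        if margin_blocked:
            reasons[ci] = R_MARGIN
            continue
        cols = [c for j in sub.indices for c in col_spans[j]]
        Xtr = Ftr[:, cols]
        try:
            model = estimators.fit(sub.indices, Xtr, y_tr)
        except estimators.FitError:
            reasons[ci] = R_FIT
            continue
        d = Xtr.shape[1]
        if linear:
            if constraints.riley_gate and not feasibility.rsq_gate_linear(
                    model.R2_app, d, n_tr, rsq_threshold):
                reasons[ci] = R_RSQ
                continue
            if constraints.marg is not None:
                try:
                    mv, mo = feasibility.margins_linear(
                        n_tr, d, model.sigma_hat, model.mean_hat)
                except ZeroDivisionError:
                    reasons[ci] = R_MARGIN
                    continue
                if max(mv - 1.0, mo) > constraints.marg:
                    reasons[ci] = R_MARGIN
                    continue
            yhat_te = estimators.predict_linear(model, Fte[:, cols])
            yhat_tr = estimators.predict_linear(model, Xtr)
            vals[ci, 0], vals[ci, 1] = metrics.abs_rel_error(outcome.encoded[test], yhat_te)
            vals[ci, 2], vals[ci, 3] = metrics.abs_rel_error(y_tr.encoded, yhat_tr)
        else:
            if constraints.riley_gate and mode == "binary" and not feasibility.riley_gate_binary(
                    model.logL0, model.logLm, d, n_tr):
                reasons[ci] = R_RILEY
                continue
            p_te = estimators.categorical_probs(model, Fte[:, cols])
            p_tr = estimators.categorical_probs(model, Xtr)
            if objective == "roc":
                vals[ci, 0] = metrics.auroc(y_te_enc, p_te[:, 1])
                vals[ci, 1] = metrics.auroc(y_tr.encoded, p_tr[:, 1])
            else:
                c = constraints.cutoff
                vals[ci, 0] = metrics.accuracy(y_te_enc, estimators.classify(p_te, mode, c))
                vals[ci, 1] = metrics.accuracy(y_tr.encoded, estimators.classify(p_tr, mode, c))

    if linear:
        emp = metrics.empirical_baseline(y_tr, outcome.restrict(test), "linear")
    elif objective == "roc":
        emp = ()
    else:
        emp = (metrics.empirical_baseline(y_tr, outcome.restrict(test), mode),)
    return vals, reasons, np.asarray(emp, dtype=float)


@dataclass
class RankingResult:
    """Averaged predictive power per model, with the ranked best models.

    ``header`` mirrors the canonical output array: for linear mode six
    numbers (best test absolute/relative error, the same model's training
    errors, empirical absolute/relative error); for the accuracy objective
    three (best test accuracy, its training accuracy, empirical accuracy);
    for AUROC two (best test, its training value).  Variable indices in
    ``best_by_metric`` and ``per_model`` are 1-based relative to the supplied
    predictor block.
    """

    mode: str
    objective: str
    header: np.ndarray
    header_names: tuple
    best_by_metric: dict
    per_model: pd.DataFrame
    empirical: dict
    crv: int
    part: int
    seed: int
    n_candidates: int
    reason_counts: dict
    config: dict = field(default_factory=dict)


def _rank_metric(means, eligible, minimize: bool):
    """Indices of all exactly-tied best models among the eligible ones."""
    ok = eligible & ~np.isnan(means)
    if not ok.any():
        return [], float("nan")
    vals = means[ok]
    best = vals.min() if minimize else vals.max()
    idx = np.flatnonzero(ok & (means == best))
    return list(idx), float(best)


def aggregate_and_rank(candidates, all_vals: np.ndarray, all_reasons: np.ndarray,
                       emp_vals: np.ndarray, mode: str, objective: str,
                       constraints: Constraints, crv: int) -> tuple:
    """Average the per-split values and rank the models.

    ``all_vals``: (crv, n_candidates, n_metrics); ``all_reasons``:
    (crv, n_candidates).  A model's average uses only the splits where it was
    evaluated; its coverage fraction must reach ``constraints.min_coverage``
    for it to be declared best.
    """
    linear = mode == "linear"
    import warnings as _w
    with np.errstate(invalid="ignore"), _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)  # all-NaN columns are legal
        means = np.nanmean(all_vals, axis=0)
    n_eval = np.sum(~np.isnan(all_vals), axis=0)
    feasible = (all_reasons == R_OK).sum(axis=0)
    coverage = feasible / crv
    eligible = coverage >= constraints.min_coverage

    emp_mean = emp_vals.mean(axis=0) if emp_vals.size else np.array([])

    one_based = [tuple(i + 1 for i in c.indices) for c in candidates]
    table = pd.DataFrame({
        "indices": one_based,
        "weight": [c.weight for c in candidates],
        "feasible_count": feasible,
        "coverage": coverage,
    })
    reason_counts = {}
    for code, label in REASON_LABELS.items():
        if code == R_OK:
            continue
        cnt = (all_reasons == code).sum()
        if cnt:
            reason_counts[label] = int(cnt)

    best_by_metric = {}
    if linear:
        table["test_abs"] = means[:, 0]
        table["test_rel"] = means[:, 1]
        table["train_abs"] = means[:, 2]
        table["train_rel"] = means[:, 3]
        idx_a, best_a = _rank_metric(means[:, 0], eligible, True)
        idx_r, best_r = _rank_metric(means[:, 1], eligible, True)
        best_by_metric["abs_error"] = [one_based[i] for i in idx_a]
        best_by_metric["rel_error"] = [one_based[i] for i in idx_r]
        header = np.array([
            best_a, best_r,
            means[idx_a[0], 2] if idx_a else float("nan"),
            means[idx_r[0], 3] if idx_r else float("nan"),
            emp_mean[0], emp_mean[1],
        ])
        names = ("best_test_abs", "best_test_rel", "best_train_abs",
                 "best_train_rel", "emp_abs", "emp_rel")
        empirical = {"abs_error": float(emp_mean[0]), "rel_error": float(emp_mean[1])}
    else:
        key = "auroc" if objective == "roc" else "accuracy"
        table["test_" + key] = means[:, 0]
        table["train_" + key] = means[:, 1]
        table["n_eval_test"] = n_eval[:, 0]
        idx, best = _rank_metric(means[:, 0], eligible, False)
        best_by_metric[key] = [one_based[i] for i in idx]
        tr = means[idx[0], 1] if idx else float("nan")
        if objective == "roc":
            header = np.array([best, tr])
            names = ("best_test_auroc", "best_train_auroc")
            empirical = {}
        else:
            header = np.array([best, tr, emp_mean[0]])
            names = ("best_test_acc", "best_train_acc", "emp_acc")
            empirical = {"accuracy": float(emp_mean[0])}
    return header, names, best_by_metric, table, empirical, reason_counts


def run(table: PredictorTable, outcome: OutcomeSpec, constraints: Constraints | None = None,
        objective: str = "acc", crv: int = 100, part: int = 10, seed: int = 0,
        n_jobs: int = 1, rsq_threshold=None, split_plan: SplitPlan | None = None,
        config_echo: dict | None = None) -> RankingResult:
    """Full analysis: splits → enumeration → per-split evaluation → ranking."""
    constraints = constraints or Constraints()
    mode = outcome.mode
    if mode == "linear" and objective == "roc":
        raise ValueError("the AUROC objective requires a binary outcome")
    if objective == "roc" and mode == "multin":
        raise ValueError("AUROC is defined for binary outcomes only")
    N = table.n_rows
    if len(outcome.encoded) != N:
        raise ValueError("outcome length does not match the predictor table")
    plan = split_plan or make_splits(N, crv, part, seed)
    if plan.n_rows != N:
        raise ValueError("split plan was built for a different sample size")
    n_tr = N - N // part

    # EPV bound on the subset weight, using the best case over splits
    if mode == "linear":
        max_events = n_tr
    else:
        max_events = int(np.min(outcome.category_counts))
    max_total_weight = feasibility.epv_max_weight(max_events, constraints.epv_rule)

    candidates = list(enumerate_subsets(table.weights, constraints, max_total_weight,
                                        table.correlation))
    # flat design matrix with per-predictor column spans
    spans, blocks, start = [], [], 0
    for j in range(table.n_columns):
        b = table.design_block(j)
        blocks.append(b)
        spans.append(list(range(start, start + b.shape[1])))
        start += b.shape[1]
    F = np.hstack(blocks) if blocks else np.empty((N, 0))

    def one(i):
        train, test = plan.splits[i]
        return evaluate_split(F, spans, outcome, train, test, candidates,
                              constraints, objective, rsq_threshold)

    if n_jobs == 1:
        results = [one(i) for i in range(plan.crv)]
    else:
        results = Parallel(n_jobs=n_jobs, prefer="threads")(
            delayed(one)(i) for i in range(plan.crv))

    n_vals = 4 if mode == "linear" else 2
    all_vals = np.stack([r[0] for r in results]) if candidates else \
        np.empty((plan.crv, 0, n_vals))
    all_reasons = np.stack([r[1] for r in results]) if candidates else \
        np.empty((plan.crv, 0), dtype=np.int8)
    emp_vals = np.stack([r[2] for r in results])

    header, names, best, per_model, empirical, reason_counts = aggregate_and_rank(
        candidates, all_vals, all_reasons, emp_vals, mode, objective, constraints, plan.crv)
    return RankingResult(mode, objective, header, names, best, per_model, empirical,
                         plan.crv, part, seed, len(candidates), reason_counts,
                         dict(config_echo or {}))
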