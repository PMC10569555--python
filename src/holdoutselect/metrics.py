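"""Predictive-power metrics and the no-covariate empirical baseline."""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["abs_rel_error", "accuracy", "auroc", "empirical_baseline"]


def abs_rel_error(y, yhat):
    """Mean absolute and mean relative prediction error.

    ``abs = mean |y - yhat|``; ``rel = mean |(y - yhat)/y|``, reported as NaN
    (propagated as NA) when any test outcome is exactly zero.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length, non-empty")
    err = np.abs(y - yhat)
    abs_err = float(err.mean())
    if np.any(y == 0.0):
        return abs_err, float("nan")
    return abs_err, float((err / np.abs(y)).mean())


def accuracy(y, yhat) -> float:
    """Fraction of exact category matches."""
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("y and yhat must be equal-length, non-empty")
    return float(np.mean(y == yhat))


def auroc(y, scores) -> float:
    """Rank-based (Mann–Whitney) AUROC with half-credit for ties.

    ``y`` holds binary codes where 1 is the positive class; returns NaN when
    the test set contains a single class.
    """
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    if y.shape != scores.shape:
        raise ValueError("y and scores must have equal length")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def empirical_baseline(train_y, test_y, mode: str):
    """The no-covariate prediction scored on the test set.

    linear: predict the training mean; returns ``(abs_error, rel_error)``.
    binary/multin: always predict code 0; returns accuracy (which drops below
    0.5 when code 0 is not the majority).  Not defined for the AUROC
    objective.
    """
    train = np.asarray(getattr(train_y, "encoded", train_y))
    test = np.asarray(getattr(test_y, "encoded", test_y))
    if train.size == 0 or test.size == 0:
        raise ValueError("training and test outcomes must be non-empty")
    if mode == "linear":
        return abs_rel_error(test, np.full(test.shape, train.astype(float).mean()))
    return accuracy(test, np.zeros(test.shape, dtype=int))
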