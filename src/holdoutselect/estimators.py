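"""Model fitting and prediction for the three outcome modes.

Linear outcomes are fitted by ordinary least squares; binary and
multi-category outcomes by maximum-likelihood multinomial logit with the
highest outcome code as the reference category.  Per-candidate fit failures
(singular designs, non-convergence, a training set missing an outcome
category) raise :class:`FitError`, which the hold-out engine records as
infeasibility for that split rather than aborting the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .data_model import OutcomeSpec

__all__ = ["FitError", "FittedModel", "fit", "predict_linear", "categorical_probs", "classify"]

MAX_ITER = 100
TOL = 1e-8


class FitError(RuntimeError):
    """A candidate model could not be fitted on this training set."""


@dataclass
class FittedModel:
    subset: tuple  # 0-based predictor positions (informational)
    mode: str
    intercept: np.ndarray  # shape () linear, (L-1,) categorical
    coef: np.ndarray  # (d,) linear, (L-1, d) categorical
    n_params: int  # fitted parameters excluding intercept(s)
    # linear diagnostics
    R2_app: float = np.nan
    sigma_hat: float = np.nan
    mean_hat: float = np.nan
    # categorical diagnostics
    logL0: float = np.nan
    logLm: float = np.nan
    n_categories: int = 0


def _fit_linear(subset, X: np.ndarray, y: np.ndarray) -> FittedModel:
    n, d = X.shape
    if n < d + 2:
        raise FitError("training set smaller than design + 2")
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < d + 1:
        raise FitError("singular design")
    resid = y - A @ coef
    rss = float(resid @ resid)
    ybar = float(y.mean())
    tss = float(((y - ybar) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    dof = n - d - 1
    sigma = np.sqrt(rss / dof) if dof > 0 else 0.0
    return FittedModel(subset, "linear", coef[0], coef[1:], d,
                       R2_app=r2, sigma_hat=float(sigma), mean_hat=ybar)


def _fit_categorical(subset, X: np.ndarray, y: np.ndarray, mode: str, L: int) -> FittedModel:
    n, d = X.shape
    counts = np.bincount(y.astype(int), minlength=L)
    if (counts == 0).any():
        raise FitError("an outcome category is absent from the training set")
    if n < d + 2:
        raise FitError("training set smaller than design + 2")
    logL0 = float(np.sum(counts[counts > 0] * np.log(counts[counts > 0] / n)))
    if d == 0:
        # intercept-only: closed form, fitted probabilities = class fractions
        freqs = counts / n
        b0 = np.log(freqs[:-1] / freqs[-1])
        return FittedModel(subset, mode, b0, np.empty((L - 1, 0)), 0,
                           logL0=logL0, logLm=logL0, n_categories=L)
    import warnings as _w
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=MAX_ITER, tol=TOL)
    with _w.catch_warnings():
        _w.simplefilter("ignore", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except Exception as exc:  # noqa: BLE001 - any solver failure is infeasibility
            raise FitError(f"logistic fit failed: {exc}") from exc
    if int(np.max(clf.n_iter_)) >= MAX_ITER:
        raise FitError("logistic fit did not converge")
    # re-parameterise to reference-last: eta_k = x.(b_k - b_ref), k = 0..L-2
    if L == 2:
        # sklearn binary coef gives the logit of class 1; class 0 vs reference 1
        B = -clf.coef_  # (1, d)
        b0 = -clf.intercept_  # (1,)
    else:
        B = clf.coef_[:-1] - clf.coef_[-1]
        b0 = clf.intercept_[:-1] - clf.intercept_[-1]
    probs = _probs_from_eta(X @ B.T + b0)
    logLm = float(np.log(np.clip(probs[np.arange(n), y.astype(int)], 1e-300, None)).sum())
    return FittedModel(subset, mode, b0, B, d * (L - 1),
                       logL0=logL0, logLm=max(logLm, logL0), n_categories=L)


def fit(subset, train_X: np.ndarray, train_y: OutcomeSpec) -> FittedModel:
    """Fit the candidate design ``train_X`` (no intercept column) to the outcome."""
    if train_y.mode == "linear":
        return _fit_linear(subset, train_X, train_y.encoded)
    return _fit_categorical(subset, train_X, train_y.encoded, train_y.mode,
                            train_y.n_categories)


def predict_linear(model: FittedModel, X: np.ndarray) -> np.ndarray:
    return model.intercept + X @ model.coef


def _probs_from_eta(eta: np.ndarray) -> np.ndarray:
    """Softmax over (eta_0, ..., eta_{L-2}, 0): reference-category multinomial
    probabilities, overflow-safe."""
    z = np.column_stack([eta, np.zeros(len(eta))])
    return softmax(z, axis=1)


def categorical_probs(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Per-row probability vectors over the L outcome categories.

    ``P(k) = exp(eta_k) / (1 + sum_l exp(eta_l))`` for non-reference ``k``;
    the reference (last) category takes the remaining mass.
    """
    if model.mode not in ("binary", "multin"):
        raise ValueError("categorical_probs requires a categorical model")
    X = np.atleast_2d(X)
    return _probs_from_eta(X @ model.coef.T + model.intercept)


def classify(probs: np.ndarray, mode: str, cutoff: float = 0.5) -> np.ndarray:
    """Deterministic category prediction.

    multin: argmax (ties to the lowest code).  binary: code 1 iff
    ``P(1) >= cutoff`` (inclusive).
    """
    probs = np.atleast_2d(probs)
    if mode == "binary":
        return (probs[:, 1] >= cutoff).astype(int)
    return np.argmax(probs, axis=1)
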