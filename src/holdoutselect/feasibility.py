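"""Sample-size admissibility gates for candidate models.

Two families of checks decide whether a model may be fitted on a given
training set:

* the events-per-variable (EPV) rule of r: a model of weight ``w`` is
  feasible only if ``r * w <= N_events``, where the event count is the whole
  training-set size for continuous outcomes and the least-likely-category
  count for categorical ones;
* shrinkage-based criteria adapted from minimum-sample-size guidance for
  prediction models: an apparent-R² bound for linear fits, the Van
  Houwelingen global shrinkage factor with a Cox–Snell R² overfitting bound
  for binary fits, and optional error margins for the residual variance,
  mean outcome and outcome proportion.
"""

from __future__ import annotations

import math

from scipy import stats

__all__ = [
    "epv_max_weight",
    "epv_feasible",
    "rsq_gate_linear",
    "margins_linear",
    "riley_gate_binary",
    "proportion_margin",
]


def epv_max_weight(events: int, r: float) -> int:
    """Largest model weight admissible under the rule of ``r``: floor(events / r)."""
    if events < 0:
        raise ValueError("events must be non-negative")
    if r <= 0:
        raise ValueError("r must be positive")
    return int(math.floor(events / r))


def epv_feasible(model_weight: int, events: int, r: float) -> bool:
    """True iff ``r * model_weight <= events``."""
    if model_weight < 0:
        raise ValueError("model_weight must be non-negative")
    return r * model_weight <= events


def default_shrinkage_threshold(p: int, n_tr: int) -> float:
    """Shrinkage-factor R² bound: 0.9 * (1 - exp(-p / (0.1 * n_tr)))."""
    return 0.9 * (1.0 - math.exp(-p / (0.1 * n_tr)))


def rsq_gate_linear(R2_app: float, p: int, n_tr: int, shrinkage_threshold=None) -> bool:
    """Apparent-R² admissibility gate for a linear fit.

    Passes iff the apparent R² exceeds both the shrinkage-factor bound
    (configurable via ``shrinkage_threshold(p, n_tr)``) and the
    apparent-vs-adjusted bound ``1 - 0.05 * (n_tr - 1 - p) / p``.
    Intercept-only models (p == 0) pass vacuously.
    """
    if p == 0:
        return True
    if n_tr <= p + 1:
        raise ValueError("training set too small for the requested model")
    thr = shrinkage_threshold or default_shrinkage_threshold
    t_shrink = thr(p, n_tr)
    t_adj = 1.0 - 0.05 * (n_tr - 1 - p) / p
    return R2_app > max(t_shrink, t_adj)


def margins_linear(n_tr: int, p: int, sigma_hat: float, mean_hat: float):
    """Error margins of the residual variance and mean outcome estimates.

    Returns ``(Mv, Mo)``: ``Mv`` is the two-sided multiplicative 95% margin
    of the residual variance, ``max(chi2_{.975,nu}/nu, nu/chi2_{.025,nu})``
    with ``nu = n_tr - p - 1``; ``Mo`` is the relative 95% margin of the mean
    outcome, ``t_{.975,nu} * sigma_hat / (sqrt(n_tr) * |mean_hat|)``.  A model
    is margin-feasible iff ``max(Mv - 1, Mo) <= marg``.

    Raises ZeroDivisionError when ``mean_hat == 0`` (relative margin
    undefined); the caller skips the model for that hold-out.
    """
    nu = n_tr - p - 1
    if nu < 1:
        raise ValueError("need n_tr - p - 1 >= 1")
    if sigma_hat < 0:
        raise ValueError("sigma_hat must be non-negative")
    mv = max(stats.chi2.ppf(0.975, nu) / nu, nu / stats.chi2.ppf(0.025, nu))
    if sigma_hat == 0.0:
        mo = 0.0
    else:
        if mean_hat == 0.0:
            raise ZeroDivisionError("mean outcome is 0: relative margin undefined")
        mo = stats.t.ppf(0.975, nu) * sigma_hat / (math.sqrt(n_tr) * abs(mean_hat))
    return mv, mo


def riley_gate_binary(logL0: float, logLm: float, p: int, n_tr: int) -> bool:
    """Shrinkage admissibility gate for a binary logistic fit.

    With ``LR = 2 * (logLm - logL0)``: requires the Van Houwelingen
    shrinkage factor ``S_VH = 1 - p / LR`` to exceed 0.9 and the absolute
    Cox–Snell overfitting bound
    ``(R2_CS / R2_CS_max) * (1 - S_VH) < 0.05`` where
    ``R2_CS = 1 - exp(-LR / n_tr)`` and ``R2_CS_max = 1 - exp(2 * logL0 / n_tr)``.
    ``LR == 0`` (no information) fails the gate.
    """
    lr = 2.0 * (logLm - logL0)
    if lr < 0:
        # numerically below null: treat as no information
        lr = 0.0
    if lr == 0.0 or p <= 0:
        return False
    s_vh = 1.0 - p / lr
    if s_vh <= 0.9:
        return False
    r2_cs = 1.0 - math.exp(-lr / n_tr)
    r2_max = 1.0 - math.exp(2.0 * logL0 / n_tr)
    if r2_max <= 0:
        return False
    return (r2_cs / r2_max) * (1.0 - s_vh) < 0.05


def proportion_margin(phi_hat: float, n: int) -> float:
    """95% error margin of an outcome proportion: 1.96 * sqrt(phi(1-phi)/n)."""
    if not (0.0 <= phi_hat <= 1.0):
        raise ValueError("phi_hat must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be at least 1")
    return 1.96 * math.sqrt(phi_hat * (1.0 - phi_hat) / n)
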