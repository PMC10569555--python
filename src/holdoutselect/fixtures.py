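"""Seeded synthetic-data generator: a download-free, statistically
controlled test bed for every stage of the pipeline.

``generate`` draws correlated Gaussian continuous predictors and multinomial
categorical ones, then builds the outcome from a sparse true linear
predictor: additive Gaussian noise in linear mode, a (reference-last)
softmax draw in the categorical modes.  ``swiss_like`` and ``pima_like``
are fixed-seed bundles whose shapes and event counts mirror the classic
worked examples (a 47-row continuous table with 5 predictors; a 200-row
binary table with 7 predictors and exactly 68 events); both are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, softmax

from .data_model import OutcomeSpec, PredictorTable, encode_outcome

__all__ = ["ScenarioConfig", "generate", "swiss_like", "pima_like"]

_LEVEL_LABELS = "abcdefghij"


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario.

    support/beta define the sparse true effects over the *continuous*
    predictors (0-based positions).  For categorical outcomes ``beta`` may
    be a (L-1, k) matrix of per-equation coefficients; a 1-D beta acts on
    the first non-reference category.  ``event_target`` calibrates the
    intercept so the achieved event proportion is close to the target.
    """

    n_rows: int = 300
    n_continuous: int = 6
    categorical_levels: tuple = ()  # e.g. (3, 4): two categorical columns
    correlation: np.ndarray | float | None = None
    support: tuple = (0, 1)
    beta: tuple = (3.0, 3.0)
    intercept: float = 0.0
    noise_sd: float = 1.0
    mode: str = "linear"
    n_categories: int = 2
    event_target: float | None = None
    seed: int = 0
    level_probs: dict = field(default_factory=dict)


def _correlation_matrix(cfg: ScenarioConfig) -> np.ndarray:
    k = cfg.n_continuous
    if cfg.correlation is None:
        return np.eye(k)
    if np.isscalar(cfg.correlation):
        rho = float(cfg.correlation)
        return np.full((k, k), rho) + (1 - rho) * np.eye(k)
    return np.asarray(cfg.correlation, dtype=float)


def _eta(X: np.ndarray, cfg: ScenarioConfig) -> np.ndarray:
    beta = np.asarray(cfg.beta, dtype=float)
    if beta.ndim == 1:
        eta = np.zeros(len(X))
        for pos, b in zip(cfg.support, beta):
            eta += b * X[:, pos]
        return eta
    raise ValueError("matrix beta must go through _eta_matrix")


def generate(cfg: ScenarioConfig):
    """Draw one synthetic (PredictorTable, OutcomeSpec) pair.

    Raises ValueError when the requested correlation matrix is not positive
    semidefinite.
    """
    rng = np.random.default_rng(cfg.seed)
    corr = _correlation_matrix(cfg)
    try:
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(corr)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix is not positive semidefinite") from exc
    X = rng.standard_normal((cfg.n_rows, cfg.n_continuous)) @ chol.T

    cols = {f"x{i + 1}": X[:, i] for i in range(cfg.n_continuous)}
    for ci, n_lev in enumerate(cfg.categorical_levels):
        probs = cfg.level_probs.get(ci, np.full(n_lev, 1.0 / n_lev))
        labels = [_LEVEL_LABELS[i] for i in range(n_lev)]
        cols[f"c{ci + 1}"] = rng.choice(labels, size=cfg.n_rows, p=probs)
    df = pd.DataFrame(cols)

    beta = np.asarray(cfg.beta, dtype=float)
    if cfg.mode == "linear":
        y = cfg.intercept + _eta(X, cfg) + rng.normal(0, cfg.noise_sd, cfg.n_rows)
    elif beta.ndim == 1:
        eta = _eta(X, cfg)
        c0 = cfg.intercept
        if cfg.event_target is not None:
            target = cfg.event_target
            c0 = brentq(lambda c: expit(c + eta).mean() - target, -30, 30)
        p1 = expit(c0 + eta)
        if cfg.mode == "binary":
            y = (rng.uniform(size=cfg.n_rows) < p1).astype(int)
        else:
            # 1-D beta drives category 0 against the rest, split uniformly
            L = cfg.n_categories
            p = np.column_stack([p1] + [(1 - p1) / (L - 1)] * (L - 1))
            y = np.array([rng.choice(L, p=row) for row in p])
    else:
        # (L-1, k) per-equation coefficients, reference-last softmax
        etas = X @ beta.T + np.atleast_1d(cfg.intercept)
        z = np.column_stack([etas, np.zeros(cfg.n_rows)])
        p = softmax(z, axis=1)
        y = np.array([rng.choice(p.shape[1], p=row) for row in p])
    table = PredictorTable.from_dataframe(df)
    return table, encode_outcome(y, cfg.mode)


def swiss_like(seed: int = 657):
    """A 47-row table with 5 continuous predictors and a continuous,
    strictly positive outcome (synthetic shape mimic of a classic fertility
    table)."""
    cfg = ScenarioConfig(n_rows=47, n_continuous=5, support=(0, 2, 3, 4),
                         beta=(4.0, -6.0, 3.0, 2.0), intercept=70.0,
                         noise_sd=5.0, mode="linear", seed=seed)
    return generate(cfg)


def pima_like(seed: int = 100556):
    """A 200-row table with 7 continuous predictors and a binary outcome
    with exactly 68 events (synthetic shape mimic of a classic diabetes
    cohort).

    Events are assigned to the 68 rows with the largest logistic latent
    utility eta - logit(u), i.e. logistic sampling conditioned on the event
    count.
    """
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((200, 7))
    eta = 1.2 * X[:, 1] + 0.8 * X[:, 5] + 0.9 * X[:, 6]
    u = rng.uniform(size=200)
    latent = eta - np.log(u / (1 - u))
    y = np.zeros(200, dtype=int)
    y[np.argsort(latent)[-68:]] = 1
    df = pd.DataFrame({f"x{i + 1}": X[:, i] for i in range(7)})
    return PredictorTable.from_dataframe(df), encode_outcome(y, "binary")
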