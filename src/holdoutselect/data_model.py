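"""Typed predictors, outcome encoding and run constraints.

Encoding conventions
--------------------
Predictors: a numeric column with five or more distinct values is treated as
continuous (weight 1); a numeric column with fewer distinct values, or any
string column, is categorical with weight ``levels - 1`` (a two-level numeric
column is ``binary`` with weight 1).  Categorical predictors enter design
matrices as indicator columns with the most frequent level as the dropped
reference.

Outcomes: a non-numeric categorical outcome is converted to integer codes
``0..L-1`` so that category frequency is non-increasing in the code — the
least frequent category receives the highest code and is the reference
category of the multinomial logit.  A numeric categorical outcome keeps its
value ordering (dense codes by ascending value, reference = highest value),
so the no-covariate baseline of "always predict 0" keeps its plain meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONTINUOUS_MIN_LEVELS = 5  # numeric columns with >= 5 distinct values are continuous

VALID_MODES = ("linear", "binary", "multin")


@dataclass(frozen=True)
class PredictorColumn:
    """One candidate predictor with its events-per-variable weight."""

    name: str
    kind: str  # {"continuous", "binary", "categorical"}
    levels: tuple = ()
    weight: int = 1

    def __post_init__(self):
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == "categorical":
            if self.weight != max(len(self.levels) - 1, 0):
                raise ValueError("categorical weight must be levels - 1")
        elif self.levels:
            raise ValueError("levels only allowed for categorical columns")


def column_weight(values, name: str = "x", force_kind: str | None = None) -> PredictorColumn:
    """Classify a raw column and assign its EPV weight.

    A constant column gets weight 0 and is excluded from the candidate set by
    the enumerator.  ``force_kind`` overrides the automatic rule (per-column
    config overrides, ``continuous`` or ``categorical``).
    """
    arr = np.asarray(values)
    if arr.size == 0:
        raise ValueError(f"column {name!r} is empty")
    if pd.isna(arr).any():
        raise ValueError(f"column {name!r} contains missing values; impute or drop first")
    numeric = np.issubdtype(arr.dtype, np.number) or np.issubdtype(arr.dtype, np.bool_)
    distinct = np.unique(arr)
    if len(distinct) == 1:
        return PredictorColumn(name, "categorical", tuple(distinct), 0)
    if force_kind == "continuous":
        if not numeric:
            raise ValueError(f"column {name!r} is non-numeric, cannot force continuous")
        return PredictorColumn(name, "continuous")
    if force_kind is None and numeric and len(distinct) >= CONTINUOUS_MIN_LEVELS:
        return PredictorColumn(name, "continuous")
    if numeric and len(distinct) == 2 and force_kind is None:
        return PredictorColumn(name, "binary")
    levels = tuple(sorted(distinct))
    return PredictorColumn(name, "categorical", levels, len(levels) - 1)


@dataclass
class PredictorTable:
    """Rectangular block of typed predictors plus their correlation matrix.

    ``values`` holds the raw columns (as a DataFrame); design matrices are
    built on demand with dummy expansion of categorical columns.  The
    correlation matrix is computed once on numeric-encoded columns (integer
    level codes for categoricals) and drives the collinearity filter of the
    subset enumerator.
    """

    columns: list
    values: pd.DataFrame
    correlation: np.ndarray = field(default=None)

    def __post_init__(self):
        if len(self.values) < 2:
            raise ValueError("need at least 2 rows")
        if self.values.isna().any().any():
            raise ValueError("missing cells are not supported")
        if self.correlation is None:
            self.correlation = self._numeric_correlation()
        self._design_cache = {}

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, type_overrides: dict | None = None) -> "PredictorTable":
        overrides = type_overrides or {}
        cols = [column_weight(df[c].to_numpy(), c, overrides.get(c)) for c in df.columns]
        return cls(cols, df.reset_index(drop=True))

    @classmethod
    def from_csv(cls, path, outcome: str | None = None, type_overrides: dict | None = None):
        """Read an RFC-4180 CSV (header required); returns (table, outcome series)."""
        df = pd.read_csv(path)
        y = None
        if outcome is not None:
            if outcome not in df.columns:
                raise ValueError(f"outcome column {outcome!r} not in CSV header")
            y = df[outcome]
            df = df.drop(columns=[outcome])
        return cls.from_dataframe(df, type_overrides), y

    @property
    def n_rows(self) -> int:
        return len(self.values)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.columns], dtype=int)

    def _numeric_encoded(self) -> np.ndarray:
        out = np.empty((self.n_rows, self.n_columns))
        for j, col in enumerate(self.columns):
            v = self.values.iloc[:, j].to_numpy()
            if col.kind == "categorical" and not np.issubdtype(v.dtype, np.number):
                codes = {lev: i for i, lev in enumerate(col.levels)}
                out[:, j] = [codes[x] for x in v]
            else:
                out[:, j] = v.astype(float)
        return out

    def _numeric_correlation(self) -> np.ndarray:
        enc = self._numeric_encoded()
        sd = enc.std(axis=0)
        corr = np.eye(self.n_columns)
        ok = sd > 0
        if ok.sum() >= 2:
            sub = np.corrcoef(enc[:, ok], rowvar=False)
            idx = np.flatnonzero(ok)
            corr[np.ix_(idx, idx)] = sub
        return corr

    def design_block(self, j: int) -> np.ndarray:
        """Design columns for predictor ``j``: the column itself, or its
        dummy indicators with the most frequent level dropped."""
        if j in self._design_cache:
            return self._design_cache[j]
        col = self.columns[j]
        v = self.values.iloc[:, j].to_numpy()
        if col.kind == "categorical":
            counts = pd.Series(v).value_counts()
            # most frequent level dropped; ties broken by level order
            ref = max(col.levels, key=lambda lev: (counts.get(lev, 0), ))
            kept = [lev for lev in col.levels if lev != ref]
            block = np.column_stack([(v == lev).astype(float) for lev in kept]) \
                if kept else np.empty((len(v), 0))
        else:
            block = v.astype(float).reshape(-1, 1)
        self._design_cache[j] = block
        return block

    def design_matrix(self, subset) -> np.ndarray:
        """Horizontal concatenation of design blocks for the given predictor
        positions (0-based), without intercept."""
        blocks = [self.design_block(j) for j in subset]
        if not blocks:
            return np.empty((self.n_rows, 0))
        return np.hstack(blocks)


@dataclass
class OutcomeSpec:
    """Outcome values with their mode and category encoding."""

    mode: str
    raw: np.ndarray
    encoded: np.ndarray
    categories: tuple = ()  # code -> original value (categorical modes)
    category_counts: np.ndarray = None
    reference_category: int = -1

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def decode(self, codes) -> np.ndarray:
        if self.mode == "linear":
            return np.asarray(codes, dtype=float)
        lut = np.asarray(self.categories, dtype=object)
        return lut[np.asarray(codes, dtype=int)]

    def restrict(self, rows) -> "OutcomeSpec":
        """Same encoding restricted to a row subset (category codes are kept,
        counts recomputed); used for per-split event counting."""
        enc = self.encoded[rows]
        if self.mode == "linear":
            return replace(self, raw=self.raw[rows], encoded=enc)
        counts = np.bincount(enc.astype(int), minlength=self.n_categories)
        return replace(self, raw=self.raw[rows], encoded=enc, category_counts=counts)


def encode_outcome(raw, mode: str) -> OutcomeSpec:
    """Encode the outcome column for the requested mode.

    linear: values pass through as floats.  binary/multin: non-numeric
    categories are coded by descending frequency (least frequent gets the
    highest code = reference); numeric categories keep their value order
    (highest value = reference).  Frequency ties break by sorted raw value.
    """
    if mode not in VALID_MODES:
        raise ValueError(f"mode must be one of {VALID_MODES}, got {mode!r}")
    arr = np.asarray(raw)
    if arr.size == 0:
        raise ValueError("outcome is empty")
    if pd.isna(arr).any():
        raise ValueError("outcome contains missing values")
    numeric = np.issubdtype(arr.dtype, np.number) or np.issubdtype(arr.dtype, np.bool_)
    if mode == "linear":
        if not numeric:
            raise ValueError("linear mode requires a numeric outcome")
        vals = arr.astype(float)
        return OutcomeSpec(mode, vals, vals)

    uniq, counts = np.unique(arr, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("categorical outcome must have at least 2 distinct values")
    if mode == "binary" and len(uniq) != 2:
        raise ValueError(f"binary mode requires exactly 2 outcome values, got {len(uniq)}")
    if numeric:
        order = np.argsort(uniq)  # ascending value: highest value -> highest code
    else:
        # descending frequency; ties by sorted raw value (uniq is sorted)
        order = np.argsort(-counts, kind="stable")
    categories = tuple(uniq[order])
    code_of = {v: c for c, v in enumerate(categories)}
    encoded = np.array([code_of[v] for v in arr], dtype=int)
    cat_counts = np.bincount(encoded, minlength=len(categories))
    return OutcomeSpec(mode, arr, encoded, categories, cat_counts, len(categories) - 1)


@dataclass(frozen=True)
class Constraints:
    """Search-space and feasibility constraints.

    epv_rule
        the rule-of-r threshold: a model of weight w needs at least
        ``r * w`` events (the whole training sample for linear outcomes,
        the least-likely-category count for categorical ones).
    riley_gate
        apply the shrinkage / R-squared sample-size criteria on each
        training fit (``Rsq=TRUE`` semantics).
    marg
        optional error margin for the residual-variance/mean (linear) or
        outcome-proportion (binary) estimates; unset disables the check.
    min_coverage
        fraction of hold-outs a model must be evaluated in before it can be
        declared best.
    """

    epv_rule: float = 10.0
    min_vars: int = 1
    max_vars: int | None = None
    max_weight: int | None = None
    forced: frozenset = frozenset()
    max_correlation: float = 1.0
    riley_gate: bool = False
    marg: float | None = None
    cutoff: float = 0.5
    min_coverage: float = 0.5

    def __post_init__(self):
        if self.epv_rule <= 0:
            raise ValueError("epv_rule must be positive")
        if self.max_vars is not None and self.min_vars > self.max_vars:
            raise ValueError("min_vars exceeds max_vars")
        if not (0.0 < self.cutoff < 1.0):
            raise ValueError("cutoff must lie in (0, 1)")
        if not (0.0 < self.max_correlation <= 1.0):
            raise ValueError("max_correlation must lie in (0, 1]")
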