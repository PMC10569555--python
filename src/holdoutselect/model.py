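"""statsmodels-style facade: a selector model built from data whose ``fit``
returns a results object carrying the ranking, diagnostics and reports."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import holdout
from .data_model import Constraints, OutcomeSpec, PredictorTable, encode_outcome
from .expansion import cub, quadr

__all__ = ["BestSubsetSelector", "BestSubsetResults"]


class BestSubsetSelector:
    """Exhaustive best-subset selector over repeated hold-out splits.

    Parameters
    ----------
    data
        DataFrame of predictor columns (plus the outcome column when
        ``outcome`` names one of them), or a ready PredictorTable.
    outcome
        Outcome column name (when in ``data``) or an explicit value array.
    mode
        "linear", "binary" or "multin".
    expand
        Optional interaction expansion of the predictor block before
        enumeration: "quadr" or "cub" (numeric predictors only).
    type_overrides
        Per-column kind overrides, name -> {"continuous" | "categorical"}.
    """

    def __init__(self, data, outcome, mode: str = "linear", expand: str | None = None,
                 type_overrides: dict | None = None):
        if isinstance(data, PredictorTable):
            table = data
            raw_y = np.asarray(outcome)
        else:
            df = pd.DataFrame(data)
            if isinstance(outcome, str):
                if outcome not in df.columns:
                    raise ValueError(f"outcome column {outcome!r} not found")
                raw_y = df[outcome].to_numpy()
                df = df.drop(columns=[outcome])
            else:
                raw_y = np.asarray(outcome)
            if expand in ("quadr", "cub"):
                design = quadr(df) if expand == "quadr" else cub(df)
                df = design.to_frame()
                self.expansion = design
            elif expand is not None:
                raise ValueError("expand must be None, 'quadr' or 'cub'")
            else:
                self.expansion = None
            table = PredictorTable.from_dataframe(df, type_overrides)
        self.table = table
        self.mode = mode
        self.expand = expand
        self.outcome: OutcomeSpec = encode_outcome(raw_y, mode)

    @classmethod
    def from_csv(cls, path, outcome: str, mode: str = "linear", expand: str | None = None,
                 type_overrides: dict | None = None) -> "BestSubsetSelector":
        df = pd.read_csv(path)
        return cls(df, outcome, mode=mode, expand=expand, type_overrides=type_overrides)

    def fit(self, crv: int = 100, part: int = 10, rule: float = 10.0,
            minx: int = 1, maxx: int | None = None, maxw: int | None = None,
            fixed=(), corr: float = 1.0, cutoff: float = 0.5,
            objfun: str = "acc", Rsq: bool = False, marg: float | None = None,
            seed: int = 0, n_jobs: int = 1, min_coverage: float = 0.5,
            rsq_threshold=None, split_plan=None) -> "BestSubsetResults":
        """Run the hold-out sweep and rank every admissible subset.

        ``fixed`` takes 1-based predictor indices (the reporting convention);
        ``part`` sets the test fraction to 1/part (training = (part-1)/part).
        """
        forced = frozenset(int(i) - 1 for i in fixed)
        if any(i < 0 or i >= self.table.n_columns for i in forced):
            raise ValueError("fixed indices must be 1..n_predictors")
        constraints = Constraints(
            epv_rule=rule, min_vars=minx, max_vars=maxx, max_weight=maxw,
            forced=forced, max_correlation=corr, riley_gate=Rsq, marg=marg,
            cutoff=cutoff, min_coverage=min_coverage)
        config = {"mode": self.mode, "crv": crv, "part": part, "rule": rule,
                  "minx": minx, "maxx": maxx, "maxw": maxw,
                  "fixed": sorted(int(i) for i in fixed), "corr": corr,
                  "cutoff": cutoff, "objfun": objfun, "Rsq": Rsq, "marg": marg,
                  "seed": seed, "min_coverage": min_coverage,
                  "expand": self.expand}
        ranking = holdout.run(self.table, self.outcome, constraints,
                              objective=objfun, crv=crv, part=part, seed=seed,
                              n_jobs=n_jobs, rsq_threshold=rsq_threshold,
                              split_plan=split_plan, config_echo=config)
        plan = split_plan or holdout.make_splits(self.table.n_rows, crv, part, seed)
        return BestSubsetResults(self, ranking, constraints, plan)


class BestSubsetResults:
    """Ranking results of a hold-out best-subset sweep.

    Attributes
    ----------
    header : ndarray
        The canonical metric array (see RankingResult).
    best_models : dict
        metric name -> list of tied best models as 1-based index tuples.
    per_model : DataFrame
        Averages, coverage and feasibility counts for every candidate.
    """

    def __init__(self, model: BestSubsetSelector, ranking: holdout.RankingResult,
                 constraints: Constraints, split_plan: holdout.SplitPlan):
        self.model = model
        self.ranking = ranking
        self.constraints = constraints
        self.split_plan = split_plan

    @property
    def header(self) -> np.ndarray:
        return self.ranking.header

    @property
    def header_names(self) -> tuple:
        return self.ranking.header_names

    @property
    def best_models(self) -> dict:
        return self.ranking.best_by_metric

    @property
    def per_model(self) -> pd.DataFrame:
        return self.ranking.per_model

    @property
    def empirical(self) -> dict:
        return self.ranking.empirical

    def best_model_names(self, metric: str | None = None) -> list:
        """Column names of the (first) best model for the given metric."""
        metric = metric or next(iter(self.best_models))
        subsets = self.best_models[metric]
        if not subsets:
            return []
        names = [c.name for c in self.model.table.columns]
        return [names[i - 1] for i in subsets[0]]

    def summary(self) -> str:
        r = self.ranking
        lines = []
        title = "Best-subset hold-out selection"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"mode: {r.mode}   objective: {r.objective}   "
                     f"hold-outs: {r.crv}   part: {r.part}   seed: {r.seed}")
        lines.append(f"rows: {self.model.table.n_rows}   "
                     f"predictors: {self.model.table.n_columns}   "
                     f"candidate models: {r.n_candidates}")
        lines.append(f"EPV rule: {self.constraints.epv_rule}   "
                     f"Rsq gate: {self.constraints.riley_gate}   "
                     f"marg: {self.constraints.marg}")
        lines.append("-" * len(title))
        for name, val in zip(r.header_names, r.header):
            lines.append(f"{name:>16s}: {val:.6f}" if np.isfinite(val)
                         else f"{name:>16s}: NA")
        for metric, subs in r.best_by_metric.items():
            shown = ", ".join(str(s) for s in subs[:5]) if subs else "none feasible"
            extra = f" (+{len(subs) - 5} tied)" if len(subs) > 5 else ""
            lines.append(f"best by {metric}: {shown}{extra}")
        if r.reason_counts:
            skips = ", ".join(f"{k}={v}" for k, v in sorted(r.reason_counts.items()))
            lines.append(f"skip reasons (model x split): {skips}")
        return "\n".join(lines)

    def to_json(self, path=None):
        """Structured report: config echo, header, best models, empirical."""
        payload = {
            "config": self.ranking.config,
            "header": {n: (None if not np.isfinite(v) else float(v))
                       for n, v in zip(self.header_names, self.header)},
            "best_by_metric": {k: [list(t) for t in v]
                               for k, v in self.best_models.items()},
            "empirical": self.empirical,
            "n_candidates": self.ranking.n_candidates,
            "skip_reason_counts": self.ranking.reason_counts,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path):
        """Flat per-model table (one row per candidate subset)."""
        df = self.per_model.copy()
        df["indices"] = df["indices"].map(lambda t: ",".join(map(str, t)))
        df.to_csv(path, sep="\t", index=False)
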