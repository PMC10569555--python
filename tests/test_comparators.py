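import numpy as np
import pandas as pd
import pytest

from holdoutselect import comparators, fixtures
from holdoutselect.comparators import (
    l1_path_model,
    overfitting_measure,
    run_comparator,
    significant_model,
    stepwise_forward_model,
    univariate_p_value,
)
from holdoutselect.data_model import PredictorTable, encode_outcome
from holdoutselect.holdout import make_splits


@pytest.fixture(scope="module")
def strong_signal():
    rng = np.random.default_rng(21)
    X = rng.standard_normal((200, 3))
    y = 5.0 * X[:, 0] + rng.normal(0, 1, 200)
    table = PredictorTable.from_dataframe(
        pd.DataFrame(X, columns=["a", "b", "c"]))
    return table, encode_outcome(y, "linear")


class TestSignificant:
    def test_univariate_p_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.standard_normal((60, 1))
        y = 0.5 * x[:, 0] + rng.standard_normal(60)
        ours = univariate_p_value(x, y, "linear")
        ref = sm.OLS(y, sm.add_constant(x)).fit().f_pvalue
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_strong_predictor_always_kept(self, strong_signal):
        table, y = strong_signal
        plan = make_splits(200, 30, 5, seed=8)
        res = run_comparator("significant", table, y, plan)
        assert all(1 in sup for sup in res.per_split_support)
        assert res.avg_test < 2.0  # far below the sd-5 empirical error

    def test_alpha_one_keeps_every_predictor(self, strong_signal):
        table, y = strong_signal
        plan = make_splits(200, 2, 5, seed=1)
        te, tr, kept = significant_model(plan.splits[0], table, y, alpha=1.0)
        assert kept == (1, 2, 3)

    def test_heterogeneous_data_gives_unstable_selection(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((120, 4))
        y = 0.25 * X[:, 1] + rng.normal(0, 1, 120)  # borderline signal
        table = PredictorTable.from_dataframe(pd.DataFrame(X, columns=list("wxyz")))
        plan = make_splits(120, 40, 4, seed=2)
        res = run_comparator("significant", table, encode_outcome(y, "linear"), plan)
        assert len(set(res.per_split_support)) >= 2


class TestStepwise:
    def test_single_strong_predictor_selected(self, strong_signal):
        table, y = strong_signal
        plan = make_splits(200, 5, 5, seed=3)
        te, tr, sel = stepwise_forward_model(plan.splits[0], table, y)
        assert 1 in sel

    def test_greedy_ic_never_beats_exhaustive_minimum(self, rng):
        from itertools import combinations

        from holdoutselect.comparators import _ic

        X = rng.standard_normal((80, 4))
        y = X[:, 0] + 0.5 * X[:, 1] * X[:, 2] + rng.normal(0, 1, 80)
        table = PredictorTable.from_dataframe(pd.DataFrame(X, columns=list("abcd")))
        spec = encode_outcome(y, "linear")
        plan = make_splits(80, 1, 4, seed=6)
        train, test = plan.splits[0]
        _, _, sel = stepwise_forward_model(plan.splits[0], table, spec)
        sel_cols = [j - 1 for j in sel]
        ic_forward = _ic(spec, X[np.ix_(train, sel_cols)], spec.encoded[train])
        ic_best = min(
            _ic(spec, X[np.ix_(train, list(combo))], spec.encoded[train])
            for k in range(0, 5) for combo in combinations(range(4), k))
        assert ic_forward >= ic_best - 1e-9

    def test_all_noise_selection_often_empty(self):
        rng = np.random.default_rng(17)
        X = rng.standard_normal((500, 6))
        y = rng.standard_normal(500)
        table = PredictorTable.from_dataframe(
            pd.DataFrame(X, columns=[f"n{i}" for i in range(6)]))
        plan = make_splits(500, 40, 5, seed=17)
        res = run_comparator("stepwise_forward", table,
                             encode_outcome(y, "linear"), plan)
        nonempty = sum(1 for s in res.per_split_support if s)
        assert nonempty / 40 < 0.6


class TestL1Path:
    def test_huge_lambda_matches_empirical_baseline(self, strong_signal):
        table, y = strong_signal
        plan = make_splits(200, 5, 5, seed=4)
        res = l1_path_model(plan, table, y, lambda_grid=[1e6])
        from holdoutselect.metrics import empirical_baseline
        emp = np.mean([
            empirical_baseline(y.restrict(tr), y.restrict(te), "linear")[0]
            for tr, te in plan.splits])
        assert res.avg_test == pytest.approx(emp, rel=1e-6)
        assert all(sup == () for sup in res.per_split_support)

    def test_tiny_lambda_matches_unpenalized_fit(self, strong_signal):
        from holdoutselect import estimators

        table, y = strong_signal
        plan = make_splits(200, 3, 5, seed=9)
        res = l1_path_model(plan, table, y, lambda_grid=[1e-8])
        full = []
        F = np.column_stack([table.design_block(j) for j in range(3)])
        for train, test in plan.splits:
            m = estimators.fit((0, 1, 2), F[train], y.restrict(train))
            yhat = estimators.predict_linear(m, F[test])
            full.append(np.mean(np.abs(y.encoded[test] - yhat)))
        assert res.avg_test == pytest.approx(np.mean(full), rel=1e-3)

    def test_sparse_support_recovered(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 8))
            y = 2.0 * X[:, 1] - 2.0 * X[:, 4] + rng.normal(0, 1, 200)
            table = PredictorTable.from_dataframe(
                pd.DataFrame(X, columns=[f"x{i}" for i in range(8)]))
            plan = make_splits(200, 8, 5, seed=seed)
            res = l1_path_model(plan, table, encode_outcome(y, "linear"),
                                lambda_grid=np.geomspace(1.0, 1e-4, 25))
            if all({2, 5} <= set(sup) for sup in res.per_split_support):
                hits += 1
        assert hits >= 4

    def test_binary_l1_runs_and_is_reproducible(self, pima_like):
        table, y = pima_like
        plan = make_splits(200, 4, 5, seed=13)
        grid = np.geomspace(0.2, 1e-3, 8)
        a = l1_path_model(plan, table, y, lambda_grid=grid)
        b = l1_path_model(plan, table, y, lambda_grid=grid)
        assert a.chosen_lambda == b.chosen_lambda
        assert np.array_equal(a.per_split_test, b.per_split_test)


class TestOverfitting:
    @pytest.mark.parametrize("test,train,metric,expected", [
        (1.0, 1.0, "abs", 0.0),
        (1.1, 1.0, "abs", 0.0909),
        (0.76, 0.8, "acc", 0.05),
        (0.9, 0.9, "roc", 0.0),
    ])
    def test_values(self, test, train, metric, expected):
        assert overfitting_measure(test, train, metric) == pytest.approx(expected, abs=1e-4)

    def test_zero_denominator_undefined(self):
        assert np.isnan(overfitting_measure(0.0, 1.0, "abs"))


def test_comparators_share_the_split_plan(strong_signal):
    table, y = strong_signal
    plan = make_splits(200, 6, 5, seed=30)
    sig = run_comparator("significant", table, y, plan)
    step = run_comparator("stepwise_forward", table, y, plan)
    assert hash(plan) == hash(plan)
    assert len(sig.per_split_test) == len(step.per_split_test) == plan.crv
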