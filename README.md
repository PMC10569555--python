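# holdoutselect

Exhaustive best-subset regression for clinical-scale prediction problems,
regularised by sample-size rules and ranked by average predictive power over
many random hold-out splits.

## The problem

In medical and epidemiological studies the sample is often moderate (tens to
a few hundred subjects) while the list of candidate predictors is long.
Fitting everything overfits; classical remedies — keeping univariately
significant variables, stepwise selection, lasso — pick different variables
for every re-draw of the data and give no direct estimate of out-of-sample
performance. `holdoutselect` instead searches **all** admissible predictor
subsets and ranks them by predictive power measured the only way that
matters: on data the model was not fitted to.

A candidate model for outcome *Y* with link *g* is

&nbsp;&nbsp;&nbsp;&nbsp;*g*(*Y*) = β₀ + Σₖ βₖ Xₖ,  over a subset S ⊆ {X₁…Xₙ}

with identity link for continuous outcomes and a reference-category
multinomial logit for binary/multi-category ones. A subset of total weight
*w* (1 per continuous/binary variable, levels − 1 per categorical variable)
is admissible on a training set with *N* events under the events-per-variable
rule of *r* only if *r·w ≤ N*, where events are the whole training sample
(continuous) or the least-likely-category count (categorical). Optional
stricter gates use apparent-vs-adjusted R², the Van Houwelingen shrinkage
factor 1 − p/LR with a Cox–Snell R² bound, and error margins for the
residual variance, mean outcome and outcome proportion. Each of `crv`
hold-outs re-draws a test set of ⌊N/part⌋ rows; every feasible model is fit
on the rest, scored on the test rows (mean absolute/relative error,
accuracy, or Mann–Whitney AUROC), and averages over the splits where a model
was evaluated decide the ranking. Pairwise and three-way interaction terms
can be added via quadratic/cubic design expansion, and significance-based,
stepwise-forward and L1-penalised baselines run inside the identical splits
for comparison.

## Worked example

```python
from holdoutselect import BestSubsetSelector, fixtures

table, y = fixtures.swiss_like()          # 47 rows, 5 continuous predictors
df = table.values.copy()
df["fertility"] = y.raw

sel = BestSubsetSelector(df, "fertility", mode="linear")
res = sel.fit(crv=1000, part=10, seed=657)
print(res.summary())
```

prints

```
Best-subset hold-out selection
==============================
mode: linear   objective: acc   hold-outs: 1000   part: 10   seed: 657
rows: 47   predictors: 5   candidate models: 30
EPV rule: 10.0   Rsq gate: False   marg: None
------------------------------
   best_test_abs: 3.579625
   best_test_rel: 0.052884
  best_train_abs: 3.261396
  best_train_rel: 0.048313
         emp_abs: 7.689059
         emp_rel: 0.114977
best by abs_error: (1, 3, 4)
best by rel_error: (1, 3, 4)
```

With 47 rows and the default rule of ten, only models of weight ≤ 4 are
admissible (30 of the 31 non-empty subsets). The first two numbers are the
average absolute and relative test-set errors of the best-performing models;
the next two are the same models' training errors (their gap measures
overfitting — here about 9% relative); the last two are the errors of the
no-covariate empirical prediction (the training mean), which the selected
model beats by a factor of two. Both error criteria pick predictors 1, 3
and 4 (1-based positions in the predictor block).

The same object handles binary (`mode="binary"`, objective `acc` or `roc`)
and multi-category (`mode="multin"`) outcomes, forced terms (`fixed=`),
weight/size/correlation bounds (`maxw=`, `maxx=`, `corr=`), the shrinkage
gates (`Rsq=True`, `marg=`), and interaction expansion (`expand="quadr"`).
A thin CLI wraps it:

```
holdoutselect data.csv --outcome y --mode binary --crv 100 --part 5 --maxw 5
```

writing a JSON report, a TSV per-model table and a log.

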