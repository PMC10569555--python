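# Methods

## Model and procedure

`holdoutselect` treats model selection as a prediction problem on a fixed
dataset. Candidate models are all subsets of the supplied predictor block;
for a continuous outcome each candidate is an ordinary least-squares fit,
for a binary or multi-category outcome a maximum-likelihood multinomial
logit in the reference-category parameterisation

P(Y = k | x) = exp(η_k) / (1 + Σ_l exp(η_l)),  k = 0…L−2,

with the reference category (code L−1) absorbing the remaining mass.
Non-numeric outcomes are coded by descending frequency so the least frequent
category is the reference; numeric outcome codes pass through in value
order, which keeps "always predict 0" meaningful as the empirical baseline.
Categorical predictors enter the design as indicator columns with the most
frequent level dropped; any fixed dummy reference spans the same fitted
subspace, so this choice affects coefficients but not predictions.

Each of `crv` hold-outs draws ⌊N/part⌋ test rows uniformly without
replacement (training fraction (part−1)/part; `part=10` reproduces the
conventional 90/10 internal-validation split). Per split and per candidate:

1. **EPV gate.** Training events are the training-set size (continuous) or
   the least-likely-category count on the training rows (categorical, so
   feasibility is genuinely split-dependent). A model of weight w passes iff
   r·w ≤ events; `rule = r = 10` by default ("one in ten").
2. **Shrinkage gates** (optional, `Rsq=True`). Linear: apparent R² must
   exceed both 0.9·(1 − exp(−p/(0.1·n_tr))) (shrinkage-factor bound; the
   published rendering of this threshold is typographically ambiguous, so
   the bound is an injectable callable — see Design choices) and
   1 − 0.05·(n_tr − 1 − p)/p (apparent-vs-adjusted R² gap < 0.05). Binary:
   with LR = 2(logL_m − logL_0), the Van Houwelingen shrinkage factor
   S = 1 − p/LR must exceed 0.9 and (R²_CS/R²_CS,max)(1 − S) < 0.05 with
   R²_CS = 1 − exp(−LR/n_tr), R²_CS,max = 1 − exp(2·logL_0/n_tr).
3. **Error margins** (optional, `marg=`). Linear: the 95% multiplicative
   margin of the residual variance, M_v = max(χ²₀.₉₇₅,ν/ν, ν/χ²₀.₀₂₅,ν)
   with ν = n_tr − p − 1, and the relative 95% margin of the mean outcome,
   M_o = t₀.₉₇₅,ν·σ̂/(√n_tr·|ȳ|); feasible iff max(M_v − 1, M_o) ≤ marg.
   The mean margin is taken on the relative scale so `marg` is unitless and
   comparable between the two; a zero training mean skips the model for that
   split. Binary/multinomial: 1.96·√(φ̂(1−φ̂)/n_tr) ≤ marg with φ̂ the
   least-likely-category proportion (φ(1−φ) is symmetric, so the choice of
   class is immaterial).
4. **Scoring.** Survivors are scored on the test rows: mean absolute and
   relative error (relative error reported as NA whenever a test outcome is
   exactly zero, rather than silently dropping points), classification
   accuracy at the `cutoff` (binary code 1 iff P(1) ≥ cutoff, inclusive;
   multinomial argmax with ties to the lowest code), or Mann–Whitney AUROC
   with half-credit for ties (splits whose test set contains one class are
   excluded from that model's AUROC average and counted).

A model's average is taken over the splits where it was evaluated, together
with a coverage fraction (evaluated splits / crv). A model must reach
`min_coverage` (default 0.5) to be declared best: averaging only over
evaluated splits would otherwise favour models feasible only on rare,
event-rich training draws, and dividing by all splits would bias error
metrics the other way. All exactly-tied best models are reported. The
empirical baseline — training mean for continuous outcomes, constant
non-event class for categorical ones — is scored on the same splits; it is
omitted under the AUROC objective, where a constant score carries no
ranking information.

## Search-space constraints

Subsets are streamed lazily in lexicographic index order with `forced`
terms required in every model, size bounds `minx`/`maxx`, weight bound
`maxw` capped by the best-case EPV bound ⌊events_max/r⌋, and a pairwise
correlation bound `corr` (inclusive; 1 accepts everything). Correlations
are computed once on the full data (numeric-encoded columns): the filter is
a search-space reduction, and per-split filtering would make the candidate
set split-dependent beyond what event counting already requires. Quadratic
and cubic expansions generate the monomial columns in the canonical order
(linears, then per-leading-index product blocks); `find_int` inverts a
flattened 1-based column index to its base-variable tuple, with an `order`
argument so the cubic layout is decodable too. The cubic block count
follows the product formula (C(k+2,3) degree-3 monomials); squares of 0/1
columns duplicate the column itself and are left to the correlation filter.

## Estimation details

Linear fits use `numpy.linalg.lstsq` on the intercept-augmented design;
rank deficiency is treated as infeasibility for that split, never an abort.
Multinomial fits use unpenalised scikit-learn logistic regression (lbfgs,
tol 1e-8, 100 iterations), re-parameterised to the reference-last
convention; non-convergence, separation-driven solver failure, or an
outcome category absent from the training rows mark the candidate
infeasible for that split with a logged reason. Intercept-only categorical
fits use the closed form (class fractions). Probabilities are evaluated via
a log-sum-exp softmax, so overflow cannot occur. Determinism: every split
draws from an RNG seeded by (seed, split index), so serial and parallel
runs (joblib over splits) are bit-identical and independent of scheduling.

## Comparator baselines

All baselines consume the same SplitPlan as the main engine. The
significance baseline keeps predictors univariately significant at
`alpha = 0.05` on each training set (linear: model-vs-null F test, computed
in closed form; categorical: likelihood-ratio χ² with d·(L−1) degrees of
freedom) and fits the joint model of the kept set; an empty set falls back
to the empirical prediction. Stepwise forward selection greedily minimises
−2·logL + 2k from the empty model. The L1 baseline fits a lasso (linear)
or L1-penalised logistic model on each training-standardised design over a
λ grid fixed across splits — default 50 log-spaced values spanning four
decades down from λ_max, the smallest penalty zeroing every coefficient on
the full data — and reports the λ with the best average test metric plus
its per-split support sets. The overfitting measure is the relative
generalisation gap: (test − train)/test for errors, (train − test)/train
for accuracy/AUROC; the raw test/train pair is always retained so an
absolute-difference summary can be formed instead.

## Synthetic data

The generator draws correlated Gaussian continuous predictors (requested
correlation matrix via Cholesky; non-PSD matrices are rejected),
multinomial categorical columns, and outcomes from the true sparse linear
predictor — additive Gaussian noise for continuous outcomes, a
reference-last softmax draw for categorical ones, with optional intercept
calibration to hit a target event proportion. Two frozen-seed bundles
mirror classic worked-example shapes: `swiss_like` (47 rows, 5 continuous
predictors, positive continuous outcome) and `pima_like` (200 rows, 7
predictors, exactly 68 events; events are assigned to the 68 largest
logistic latent utilities, i.e. logistic sampling conditioned on the event
count). Both are synthetic stand-ins: they reproduce dimensions and event
counts, not the original measurements, so tests against them validate
mechanics and arithmetic, not the historical numeric outputs. What the
generator does not emulate: missing data, measurement error, heavy-tailed
or heteroscedastic noise, and real-world predictor dependence structures —
passing tests therefore demonstrate correctness of the procedure, not
performance guarantees on real cohorts.

## Problem sizes

The test suite runs its simulations at deliberately modest sizes chosen to
exercise every code path with stable statistics: enumeration fuzzing at
n ≤ 12 predictors against a brute-force power-set oracle, engine runs at
47–500 rows with 5–800 hold-outs, parameter-recovery sweeps over 20
generator seeds at n = 300 with 200 hold-outs, and comparator type-I
calibration over 2000 split-predictor trials.

## Known limitations

* Repeated hold-out validates **within** one dataset. A variable whose
  sample correlation with the noise (order 1/√n) happens to be large in
  that dataset genuinely improves prediction on every test subset of the
  same data, so the top-ranked model frequently augments the true support
  with one or two such variables; in the package's own recovery sweeps the
  best subset always contained the true support but equalled it exactly in
  fewer than half the seeds, and an independent brute-force re-ranking
  reproduces the same behaviour. Exact support identification requires
  external replication, not more internal splits.
* Exhaustive search is exponential in the weight bound: Σᵢ C(n, i) models
  per split. The EPV rule keeps this tractable at clinical scale; for wide
  designs a pre-screen (e.g. the L1 comparator) is the intended workflow.
* Survival outcomes, imputation, ordinal-specific encodings, multi-class
  AUROC and calibration metrics are out of scope.
* The binary/multinomial solver treats separation as split-level
  infeasibility rather than fitting with penalisation, matching the
  unpenalised-likelihood definition of the shrinkage gates.
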