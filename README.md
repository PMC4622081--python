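# survshuffle

Monte Carlo assessment of the **information content of predictor
assemblages** in right-censored survival models.

A model built on many molecular measurements can show an impressive
concordance index and still know nothing: with dozens of covariates and
a few hundred patients, a Cox model will happily overfit noise.
`survshuffle` quantifies what a *group* of variables actually
contributes by building an explicit empirical null: every targeted
variable is permuted independently across patients — destroying both
variable–outcome and variable–variable correspondence — the model is
refit on each of N randomised datasets, and the real model's Harrell
c-index is located inside the null distribution.  The one-tailed
p-value is

    p = #{ randomised datasets with c-index ≥ observed } / N .

Shuffling *all* variables measures a whole assemblage; shuffling only a
candidate group inside a combined model (the **added-value test**)
measures that group's contribution in the context of the variables that
are kept — e.g. what a proteomic panel adds on top of routine
clinicopathological staging.  This is deliberately different from a
conventional permutation test, which shuffles only the outcome and
leaves the correlation structure among predictors intact.

The package is aimed at biostatisticians and computational biologists
evaluating prognostic models that mix clinical and molecular data.  It
ships everything needed to run the analysis end-to-end:

- `coxph` — Cox proportional hazards fitting by Newton–Raphson on the
  Breslow partial likelihood, with Schoenfeld-residual diagnostics;
- `concordance` — Harrell's c-index with exact pair enumeration;
- `lasso_selection` — L1-penalized Cox feature selection
  (proximal-Newton coordinate descent, penalty chosen by likelihood
  cross-validation), followed by an unpenalized refit;
- `crossval` — repeated k-fold cross-validation and an
  optimism-corrected c-index;
- `montecarlo` — the shuffling test itself, with a pluggable evaluator
  (anything mapping a patient table to a scalar statistic);
- `synthetic` — a generator of realistic cohorts (clinicopathological
  categoricals plus 0–255-scale proteomic intensities, Weibull
  proportional-hazards outcomes, calibrated censoring) with known
  ground truth;
- `datamodel_io` / `cli` — CSV + YAML-schema I/O, JSON reports and a
  command-line interface.

## Worked example

```python
from survshuffle import (GeneratorConfig, generate, encode, fit_cox,
                         risk_scores, cindex, ShufflePlan, mc_test,
                         added_value_test, CoxCindexEvaluator, cross_validate)

table = generate(GeneratorConfig(n_patients=339, seed=1))   # synthetic cohort

for group in ("clinicopathological", "proteomic"):
    sub = table.subset(table.group_variables(group))
    design = encode(sub)
    fit = fit_cox(design, sub.outcome)
    c = cindex(risk_scores(fit, design), sub.outcome)
    plan = ShufflePlan(tuple(v.name for v in sub.variables),
                       n_permutations=1000, seed=1)
    mc = mc_test(sub, plan, CoxCindexEvaluator())
    print(f"{group}: apparent c-index {c.cindex:.3f}, MC p = {mc.formatted_pvalue()}")

av = added_value_test(table, "clinicopathological", "proteomic",
                      CoxCindexEvaluator(), n_permutations=1000, seed=1)
print(f"combined model, proteomics shuffled: c-index {av.observed_statistic:.3f}, "
      f"added-value p = {av.formatted_pvalue()}")
cv = cross_validate(table, folds=10, repeats=10, seed=1)
print(f"combined model: apparent {cv.apparent_cindex:.3f}, "
      f"cross-validated {cv.mean_cv_cindex:.3f}, corrected {cv.corrected_cindex:.3f}")
```

Output:

```
clinicopathological: apparent c-index 0.640, MC p = < 0.001
proteomic: apparent c-index 0.683, MC p = < 0.001
combined model, proteomics shuffled: c-index 0.730, added-value p = < 0.001
combined model: apparent 0.730, cross-validated 0.682, corrected 0.679
```

The default generator plants real signal in both groups (stage and
histology dominate the clinical group; five proteomic markers carry
modest effects), so every assemblage is informative: each all-variable
shuffle p-value is below 1/N, and shuffling only the proteomics inside
the combined model confirms the panel adds information beyond the
clinical variables.  The corrected c-index (0.679) sits close to the
apparent one (0.730), i.e. modest optimism.

Contrast that with pure noise, where apparent performance is an
overfitting artefact and the shuffling test says so:

```python
from survshuffle import noise_table
table = noise_table(100, 40, seed=2)        # 40 noise variables, n = 100
```

```
40 noise variables, n=100: apparent c-index 0.751, cross-validated 0.533, MC p = 0.477
```

The apparent c-index of 0.751 collapses to 0.533 under
cross-validation, and the Monte Carlo p-value of 0.477 shows the real
data discriminate no better than randomly reassigned data: the
assemblage has no information content.

## Command line

```sh
survshuffle simulate --n-patients 339 --seed 1 --out cohort.csv
survshuffle fit --input cohort.csv --schema cohort.schema.yaml --out fit.json
survshuffle mc --input cohort.csv --schema cohort.schema.yaml \
    --groups proteomic --n-permutations 10000 --seed 1 --out mc.json
survshuffle added-value --input cohort.csv --schema cohort.schema.yaml \
    --base-group clinicopathological --added-group proteomic --out av.json
survshuffle study-workflow --input cohort.csv --schema cohort.schema.yaml \
    --out report.json
```

`study-workflow` runs the full four-analysis pattern — each group
alone, the combined model with added-group shuffling, repeated with and
without LASSO feature selection — and writes a single JSON report with
c-indices, cross-validation summaries, Monte Carlo p-values and
histogram data.

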