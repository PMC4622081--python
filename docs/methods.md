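# Methods

## The question the package answers

Given a cohort with a right-censored survival outcome and a mix of
predictor groups — e.g. routine clinicopathological measures and a panel
of quantitative proteomic intensities — does a given *assemblage* of
variables actually carry prognostic information, or is its apparent
discriminative performance an artefact of overfitting?  The package
answers this with an explicit resampling null: permute each targeted
variable independently across patients, refit the model on each
randomised dataset, and locate the real model's performance inside the
resulting null distribution.

## Model and statistic

The workhorse model is Cox proportional hazards regression.  For
coefficients β and design matrix X the partial log-likelihood with
Breslow tie handling is

    ℓ(β) = Σ_t [ Σ_{i∈D_t} η_i − |D_t| · log Σ_{j∈R_t} exp(η_j) ],

where η = Xβ, the sum runs over distinct event times t, D_t is the set
of patients failing at t and R_t = {j : t_j ≥ t} the risk set.  Tied
event times share one risk-set denominator (the Breslow convention; the
Efron alternative is deliberately not implemented).  ℓ is concave and is
maximized by Newton–Raphson with step-halving; convergence is declared
when the score max-norm falls below 1e−8 (at most 50 iterations, at most
20 halvings per step).  A coefficient passing |β_j| > 20 aborts the fit
with a divergence error naming the column — a simple, conservative
detector of monotone likelihood (a column perfectly separating the event
order).  Constant columns are held at zero (the partial likelihood is
translation invariant) and the fit is flagged degenerate; a singular
information matrix triggers a tiny ridge (1e−8 × max diagonal), also
flagged.  Standard errors come from the inverse observed information at
the optimum.

Discrimination is summarized by Harrell's concordance index on the risk
scores η: among *comparable* pairs (the earlier patient had the event;
two censored patients, or tied times with two events, are incomparable;
a tied time with exactly one event counts the event patient as earlier)
it is the fraction ordered correctly, ties in score counting 1/2.  The
implementation enumerates all pairs directly; at n of a few hundred this
is exact and takes well under a millisecond.

Proportional hazards is checked through Schoenfeld residuals: the
residual of each event is the failing patient's covariate vector minus
the exp(η)-weighted risk-set mean.  Each column's residuals are
correlated against the rank of the event time (Pearson test); the rank
transform is one of several common choices and is fixed here for
determinism.  The global statistic sums squared per-column t-statistics
against a χ²_p reference — an approximation that treats columns as
independent, adequate as a screen (the calibration test uses
uncorrelated covariates for exactly this reason).

## The Monte Carlo information-content test

For a shuffle plan targeting variables S, each randomised dataset k
replaces every targeted variable's raw column by an independently seeded
permutation of itself.  Raw values are permuted *before* categorical
encoding, so a categorical variable's indicator columns always move
together.  Per-draw permutations are seeded from (master seed, draw
index, variable index), making results independent of evaluation order
and bit-reproducible.

The evaluator — any deterministic map from a patient table to a scalar
performance statistic; the shipped one is Cox + c-index — is applied to
the real table (observed statistic s₀) and to the N randomised tables
(s₁…s_N).  The one-tailed p-value is

    p  = #{k : s_k ≥ s₀} / N        (ties count toward the numerator)
    p⁺ = (#{k : s_k ≥ s₀} + 1) / (N + 1).

The plain proportion is the primary report; the add-one variant is
always computed alongside because the plain version can be exactly zero,
which formatted output renders as "< 1/N".  Under exchangeability p⁺ is
exactly super-uniform, so rejecting when p⁺ ≤ α controls type-I error;
the calibration studies confirm the empirical rejection rate at α = 0.05
is at its nominal value.  Evaluator failures on randomised data (e.g. a
diverging fit) are excluded with N reduced and the count reported rather
than retried — retrying would bias the null toward convergent
configurations; more than 5% failures abort the analysis.

Shuffling **all** variables measures the information content of the
whole assemblage.  The *added-value* variant keeps a combined model but
shuffles only a candidate group, measuring that group's contribution in
the context of the retained variables.  Both differ fundamentally from
outcome-only permutation, which preserves the correlation structure
among predictors: when predictors are duplicated or strongly dependent,
independent per-variable shuffling raises the effective rank of the
null design and the two null distributions separate measurably (the
test suite demonstrates this on exactly duplicated predictors; in our
experiments the per-variable null has the *higher* mean apparent
c-index, because the shuffled design offers more independent directions
to overfit).

When the evaluator includes feature selection, the selected set is by
default frozen from the unshuffled data and only the values are
shuffled per draw; a reselect-per-shuffle mode re-runs selection on
every randomised dataset for a more conservative null.  The default N is
10,000; calibration studies use small N (199) with many outer replicates
instead, which estimates rejection *rates* far more efficiently than a
few huge-N runs.

## Feature selection

L1-penalized Cox regression maximizes ℓ(β) − λ·Σ|β_j| with columns
standardized to zero mean and unit variance before penalization (so
0–255-scale intensities and 0/1 indicators shrink comparably) and
coefficients mapped back to the original scale afterwards.  Each
indicator column is penalized separately (no group penalty).  The solver
is proximal Newton: cyclic coordinate descent with soft-thresholding on
the local quadratic model, then a step-halving line search on the true
penalized objective; convergence is declared on the
Karush–Kuhn–Tucker conditions (|score_j| ≤ λ at zeros, score_j =
λ·sign(β_j) at nonzeros, tolerance 1e−7), which the test suite asserts
independently at 1e−6.

λ is chosen on a log-spaced grid strictly inside (0.001, 50) — 100
points by default — by k-fold likelihood cross-validation using the
verification likelihood ℓ_full(β̂_fold) − ℓ_train(β̂_fold), summed over
folds; ties go to the larger (sparser) penalty.  An empty selection is a
valid outcome.  Selected features are refit *unpenalized* downstream:
selection-then-refit, not penalized prediction.

## Cross-validation and the corrected c-index

Repeated k-fold cross-validation (defaults: 10 folds, 100 repeats)
reports the mean held-out c-index and an optimism-corrected c-index:
per fold, optimism = (c-index of the fold-trained model on its own
training data) − (its held-out c-index), and

    corrected = apparent(full data) − mean(optimism).

When selection is active it is re-run inside every training split, so
held-out folds never inform the selected set.  Fold partitions are
seeded shuffles; a partition leaving any fold (or training set) without
events is redrawn up to 10 times.  Folds must contain at least two
patients — leave-one-out is not supported because a singleton fold has
no comparable pairs.  The overfitting flag comes from a two-sided
one-sample t-test of (apparent − held-out fold c-indices) against zero
at α = 0.05; fold c-indices are not independent, so this is a screening
heuristic, not an exact test.

## Synthetic cohorts

The generator emulates the structure of a 339-patient ovarian-cancer
cohort: age in days (entered both continuously and stratified at
50 years — both forms are kept as separate variables, restrictable via
the schema), histopathology (6 levels, papillary serous most frequent),
stage (4 levels, stage 3 dominant), regimen (platinum vs platinum +
taxane), and 20 proteomic intensities on the 0–255 AQUA scale, each
tied to a nuclear or cytoplasmic compartment (ERβ1/ERβ2 appear in
both).  Proteomic marginals are truncated Gaussians (mean 100, sd 40,
support [0, 255]); an optional Gaussian copula imposes a correlation
structure on the proteomic block.

Event times follow a Weibull proportional hazards model, sampled by
inverse transform: S(t|x) = exp(−(t/b)^a · e^{x'β}).  Defaults a = 1.2
(rising hazard, still proportional) and b = 733 days put the median
event time near 540 days at η = 0 — a plausible progression-free
survival scale chosen once, not fitted to anything.  The default ground
truth concentrates signal in the clinicopathological group (stage and
histology dominate) and gives five proteomic markers modest per-unit
effects with literature-consistent signs (E-cadherin, cleaved caspase-3
and nuclear β-catenin protective; pH2AX and WT1 adverse); everything
else is exactly null.  Linear predictors are centred so the baseline
scale keeps its interpretation.

Censoring is independent exponential with its rate solved (Brent's
method) so that the conditional expected censored fraction given the
drawn event times equals the target (default 0.30); the realized
fraction is checked and the censoring redraw repeated up to 10 times
until it lands within ±0.05, else an error.  The joint generator makes
an OS-like outcome from the PFS-like one by adding independent positive
gaps to both the latent event and censoring times, which guarantees
observed OS ≥ observed PFS patient-by-patient.

What the generator does *not* emulate: real covariate distributions and
inter-marker correlations of any particular cohort, informative
censoring, missing data, measurement batch effects, or integer-day
rounding of times (times are kept continuous to avoid artificial tie
inflation).  Passing calibration tests therefore demonstrate the
statistical machinery is correct under its stated assumptions, not that
any particular biological dataset satisfies them.

## Problem sizes in the test and acceptance studies

Calibration and power studies use N = 199 permutations with hundreds of
outer replicates (500 for the global-null calibration, 200 for power
and added-value studies, 100 for the overfitting dissociation and
selection recovery); oracle comparisons use 50–100 random small
instances (n ≤ 40, p ≤ 3 for the derivative-free Cox oracle).  The
selection studies use a 25-point penalty grid spanning the same
(0.001, 50) interval as the 100-point default.  The acceptance script
re-runs the same studies at moderately reduced replicate counts; all
sizes are recorded in its JSON output.

## Known limitations

- Breslow tie handling only; with heavily tied data Efron is usually
  preferred and will differ.
- No stratified Cox, time-varying covariates or frailty terms.
- The global Schoenfeld statistic ignores covariate correlation.
- The LASSO path solver targets p in the dozens, not thousands; there
  is no pathwise screening rule.
- Monte Carlo runs are serial; at the default N = 10,000 with a
  selection-inside-CV evaluator, runtimes are dominated by the
  evaluator, not the shuffling.
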