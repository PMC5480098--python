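# Methods

## The problem

Penalized regression (LASSO-type estimators) is routinely used to select
outcome-associated predictors in biomedical data, and the selected
coefficients are then often interpreted substantively — with standard
errors and confidence intervals computed *as if* the model had been fixed
in advance. Model selection invalidates those naive asymptotics: the
post-selection sampling distribution of the estimates is non-normal and
depends on the unknown coefficients. This package quantifies the damage
by Monte-Carlo simulation under a known sparse truth, for linear and
logistic (case-control) regression, across a panel of popular selection
estimators and two inference strategies.

## Generating model

`p = 50` predictors (`p = 500` in the high-dimensional variant), of which
`p* = 10` carry signal. All signal coefficients share one magnitude
`b ∈ {0.25, 0.5, 1.0}`; the first five are `+b`, the next five `−b`
(a fixed convention — the metrics are symmetric in sign; the balanced
signs keep the linear predictor centred). Predictors are multivariate
normal with mean zero and one of three correlation structures —

* identity;
* block: disjoint 5×5 exchangeable blocks with off-diagonal 0.5
  (eigenvalues 3 and 0.5, so positive definite). Note the signals occupy
  blocks 1–2 entirely, so signals are mutually correlated but
  independent of every noise predictor;
* truncated AR: `0.5^|i−j|`, set to zero beyond lag 10 (verified
  positive definite at p = 50; an aggressive truncation can lose
  definiteness, which is detected and reported, with an optional
  nearest-PD repair);

or independent Bernoulli(0.5) for the binary-predictor logistic designs.

Linear outcomes are `y = β₀ + Xβ + ε` with `ε ~ N(0, 1)` or, as
robustness violations, Student t with 2 or 15 df, used **unscaled**
(t(2) has no finite variance, so no variance standardisation exists).
The linear intercept defaults to 0 (configurable). Logistic outcomes use
a case-control design: population units with
`Y ~ Bernoulli(expit(−1 + Xβ))` are drawn until exactly `n1` cases and
`n0` controls are collected (equal counts in the study grid); a cap of
10⁶ population draws guards degenerate configurations. Case-control
sampling biases only the intercept, so slope inference is the object of
study.

Seeding is hierarchical: replicate `r` of a cell derives data and
CV-fold seeds from `SeedSequence((master_seed, crc32(cell_key), r))`,
making every replicate individually reproducible and the results
invariant to execution order.

## Estimators

All methods share fivefold cross-validation with the minimum-CV rule
(squared error / binomial deviance), a geometric 50-point lambda path
from the null-model threshold `λ_max = max_j |x_j'(y − ȳ)|/n` down to
`10⁻³ λ_max`, an always-unpenalized intercept, and a support defined by
`|β̂_j| > 10⁻⁸` (path solvers produce exact zeros). Fold assignment
depends only on `(n, fold seed)`, so every method sees the same folds
within a replicate.

* **lasso** — L1 path; linear via scikit-learn's `lasso_path`, logistic
  via the package's coordinate-descent solver (below).
* **lars** — least-angle regression (LAR, no lasso modification);
  CV over the number of path steps.
* **enet** — the *corrected* elastic net: the naive solution of
  `(1/2n)‖y − Xβ‖² + λ₁‖β‖₁ + (λ₂/2)‖β‖²` rescaled by `(1 + λ₂)`,
  computed exactly as the LARS path of a ridge-augmented design; CV over
  `λ₂ ∈ {0, 0.01, 0.1, 1, 10, 100}` and 21 equally spaced L1 arc-length
  fractions `s ∈ [0, 1]`. The correction matters: it undoes the double
  shrinkage, which lets CV prefer ridge-heavy solutions when signals are
  mutually correlated (the block design), where the grouped signals then
  separate cleanly from noise along the path — reproducing the
  qualitative contrast between the block and independence designs. The
  uncorrected mixing-grid formulation does not show this separation
  nearly as strongly.
* **relaxo** — relaxed LASSO: stage-1 lasso support at λ, stage-2 lasso
  on that support at `φλ`, CV over `(λ, φ)` with
  `φ ∈ {0, 0.25, 0.5, 0.75, 1}`; `φ = 0` is an unpenalized refit,
  `φ = 1` the plain lasso. Stage-2 work is grouped by the (repeating)
  stage-1 supports and warm-started.
* **scad** — one-step SCAD by local linear approximation: weights
  `w_j = p'_λ(|β̂_init,j|)` with the SCAD derivative (`a = 3.7`), initial
  estimate OLS / unpenalized MLE when `n > p` (ridge otherwise,
  flagged), then one weighted-L1 solve; CV over λ. Coefficients with
  `|β̂_init,j| > aλ` get weight zero and are unshrunk.
* **penalized** — combined L1/L2 GLM: an L1 path profiled against each
  value of a small absolute ridge grid `{0.01, 0.1, 1}`, CV jointly;
  pure-L1 and pure-L2 variants available behind flags.
* **stepplr** — forward stepwise ridge-penalized logistic regression:
  candidates ranked each step by the Rao score statistic from the
  current fit, the best candidate accepted if it lowers
  `deviance + log(n)·(model size)`; ridge λ chosen once by CV on the
  full model. The score-statistic preselection fits one ridge model per
  accepted step instead of one per candidate, which changes nothing
  about the accepted sequence in practice (the score statistic is the
  standard forward-selection criterion) and keeps the method tractable
  at simulation scale.

Penalized partial least squares is not implemented: no acceptance
quantity depends on it and there is no defensible reading of how it
should yield exact zeros.

### The internal solver

Linear-family paths use scikit-learn (`lasso_path`, `lars_path`).
The logistic paths and all weighted-L1 problems use a package-authored
glmnet-style solver (`postsel.estimators._solver`): cyclic coordinate
descent with active-set iteration on the weighted gaussian objective,
wrapped in IRLS for the logistic family, warm-started along the path,
JIT-compiled with numba. Reasons: per-coefficient penalty factors (the
SCAD LLA) are not available in scikit-learn, and a warm-started compiled
path is roughly an order of magnitude faster than saga at the replicate
counts used here. The solver agrees with scikit-learn's `Lasso` and
(l1-penalized) `LogisticRegression` to ~10⁻⁶ and with closed-form ridge
solutions to ~10⁻⁸ in the unit suite; dense ridge/MLE logistic fits use
a damped Newton routine checked against statsmodels.

## Post-selection inference

For a fitted support S, the selected design is `X_S = [1, X_j : j ∈ S]`
with `p_adapt = 1 + |S|` columns.

* **Adaptive (Algorithm 1)**: keep the penalized estimates
  `β̂_adapt = (β̂₀, β̂_S)`. Linear: `σ̂²_adapt = ‖y − X_S β̂_adapt‖² /
  (n − p_adapt)` and covariance `σ̂²_adapt (X_S'X_S)⁻¹`. Logistic:
  covariance `(X_S' V̂ X_S)⁻¹` with `V̂ = diag(p̂ᵢ(1−p̂ᵢ))` at the
  penalized estimates (probabilities clipped at 10⁻¹⁰, flagged).
* **Oracle (Algorithm 2)**: refit unpenalized on `X_S` (least squares /
  logistic MLE via statsmodels GLM) and use the standard covariance.
  The linear point estimates depend on the support only, not on the
  stage-1 coefficient magnitudes.

Wald intervals `β̂_j ± z_{0.975} √(cov_jj)`. Degrees of freedom count
the intercept inside `p_adapt`. Degenerate replicates — `p_adapt ≥ n`,
singular selected design, complete or quasi-complete separation
(detected by diverging estimates `|β̂| > 30` or exploding variances) —
are flagged, tallied, and excluded from coverage numerators and
denominators rather than silently dropped. Matrix inverses go through a
Cholesky factorization with a condition-number warning at 10¹².

## Performance criteria

All rates average per-coefficient over replicates first, then over the
relevant coefficient set:

* **FP rate** — truly-zero coefficient estimated nonzero; **FN rate** —
  truly-nonzero estimated zero.
* **Coverage of zero** (per algorithm, separately for true zeros and
  true signals) — the coefficient is dropped, or its CI contains 0.
* **Coverage of the truth** (per algorithm) — among replicates where the
  signal coefficient was *selected*, the fraction whose CI contains the
  true value (the selection-conditional reading matching the results
  tables' "for β̂ ≠ 0" columns; the unconditional variant, which
  conflates non-selection with non-coverage, is available behind a
  flag). A coefficient never selected contributes no term and is logged.

A long-format audit log (replicate × coefficient events) can be exported
and every metric recomputed from it by independent counting; the test
suite does this recount exactly.

## Problem sizes and tolerances

The replicate counts used in the acceptance checks are 200–500 per cell
(300 for the logistic coverage cells, 500 for the linear heavy-tail FP
cell, 200 elsewhere, 2000 for the distribution-free OLS coverage check),
with comparisons at the binomial Monte-Carlo tolerance
`3·sqrt(v(1−v)/R)`, widened to an absolute 0.05 floor for
quantities that move with the CV tuning intensity (selection rates and
selection-conditional coverages). The grid CLI defaults to R = 1000 per
cell for full reproductions.

## Known limitations

* CV-tuning intensity is a genuine degree of freedom: the original
  study's software stack tuned some methods differently than the
  minimum-CV convention used uniformly here, and selection rates (hence
  selection-conditional coverages) shift by a few points with that
  choice. The linear-family cells reproduce the published values
  closely; the logistic LASSO cell selects somewhat more noise than
  published (FP ≈ 0.51 vs 0.443), with correspondingly lower adaptive
  coverage.
* The synthetic designs have exactly unit-variance predictors and
  homogeneous effect magnitudes; real data have scale heterogeneity,
  which interacts with penalty standardisation in ways these simulations
  do not probe.
* Only the intercept-biased case-control design is simulated for the
  logistic family; prospective sampling is not.
* The p > n variant restricts to the path methods that remain stable
  there (lasso, LARS, relaxed LASSO; ridge-initialised SCAD behind a
  flag), mirroring the failure pattern of the other estimators.
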