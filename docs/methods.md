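# Methods

## Model and estimands

The package measures wealth-related inequality in a binary health outcome
$h$ (the motivating application is regular antenatal care, defined as four
or more visits) over a survey of births with sampling weights $w_i$.

**Wealth ranking.** Household economic status is proxied by the first
principal component of the asset indicator matrix. Indicators are
standardized with weighted means/SDs and projected on the leading
eigenvector of the weighted correlation matrix; constant indicators are
dropped with a warning. The score's sign is oriented so that a designated
"richer" indicator (default in the pipeline: the modern-toilet dummy;
fallback: the household's total asset count) correlates positively with it.
The equity stratifier is the weighted fractional rank
$r_i = (W_{<i} + w_i/2)/W$, with tie groups sharing their weighted mean
rank; this keeps the weighted mean of $r$ at exactly 0.5 under any
weighting. Quintiles use cumulative-weight cut points, whole tie groups
assigned to the lower quintile when they land on a cut.

**Concentration index.** $\mathrm{CI} = 2\,\mathrm{cov}_w(h,r)/\mu$ with
the population (divide-by-total-weight) covariance convention. This
convention, rather than $n-1$, is what makes the decomposition identities
exact. For bounded variables the Erreygers normalization
$E = 4\mu\,\mathrm{CI}/(b-a)$ is computed; bounds are auto-detected as
$(0,1)$ for binary data and left undefined otherwise. The generalized
concentration index $GC_e = 2\,\mathrm{cov}_w(e,r)$ of model residuals
carries the unexplained component $GC_e/\mu$.

**Decomposition.** With a linear-additive model of the outcome, $\mathrm{CI}
= \sum_k \eta_k C_k + GC_e/\mu$ where $\eta_k = \beta_k\bar x_k/\mu$. Two
outcome models are provided:

* **logit** (default): weighted maximum likelihood via IRLS; $\beta_k$ is
  replaced by the average marginal effect — for a 0/1 regressor the
  weighted mean discrete change $p(x_k{=}1)-p(x_k{=}0)$, for a continuous
  regressor the weighted mean of $p_i(1-p_i)\beta_k$. An `me_at_means`
  switch evaluates effects at the weighted covariate means instead. Under
  this linearization additivity holds only approximately; the gap is
  reported as the residual.
* **lpm**: weighted least squares; marginal effects are the coefficients
  and $\sum_k \eta_k C_k + GC_e/\mu = \mathrm{CI}$ holds to machine
  precision (asserted at 1e-10 in the tests).

Percent contributions are shares of the explained part
$\widehat{\mathrm{CI}} = \sum_k \eta_k C_k$, not of the total CI — this is
the normalization consistent with the benchmark's printed percentages — and
the residual is reported separately, on both the standard and the
Erreygers scale (shares scale by $4\mu$; percentages are scale-invariant).
A determinant with zero weighted mean has no defined elasticity scale; its
contribution is forced to 0 with a warning.

**Change decomposition.** Between waves A (early) and B (late), each
determinant's contribution change $\eta_{kB}C_{kB}-\eta_{kA}C_{kA}$ splits
exactly into an elasticity-change and an inequality-change component. Both
classical reference weightings are first-class:
`table4` = $C_{kB}\Delta\eta_k + \eta_{kA}\Delta C_k$ (default) and
`paper` = $C_{kA}\Delta\eta_k + \eta_{kB}\Delta C_k$. They differ per row
by exactly $-\Delta\eta_k\,\Delta C_k$, which the tests use as a
cross-check. The default is the weighting that reproduces the benchmark's
printed change table cell-by-cell; the benchmark's own displayed equation
corresponds to `paper`, and the discrepancy is surfaced rather than hidden
(both are computed, the scheme is logged). Percent shares divide each
component by the explained total change; since the change is computed late
minus early, a determinant "contributed to the decline" of a falling
positive CI exactly when its percent share is positive, and those rows are
flagged in the result's `attrs`.

## Recoding conventions

Determinants follow the benchmark variable set: five-year age-at-birth
dummies (reference 15–19), own and husband's education (reference: no
education), six regions (reference: urban governorates), modern-toilet
dummy, terminated-pregnancy dummy, preceding birth interval > 24 months
(strict), single birth, birth order (count), and previous-birth dummies
(medical delivery, caesarean, previous child alive). First-order births
have no preceding interval; the default codes them as adequate (> 24
months), since no short-interval risk is present, with a `short` switch; it
also codes the previous-birth dummies 0, with an optional explicit
`no_previous_birth` indicator.

## Synthetic data generator

One latent standard-normal wealth factor $z$ per household drives
everything. Each asset and covariate is linked to $z$ through a Gaussian
copula: a variable with marginal prevalence $p$ and loading $\rho$ is
generated from $u = \rho z + \sqrt{1-\rho^2}\,\epsilon$ thresholded at the
appropriate normal quantile, so marginals are exact by construction and
$\rho$ controls how pro-rich or pro-poor the variable is. Ordered
categories (education, age band, region ordered poorest→richest) use the
same latent $u$ with quantile bands; birth order is $1+\mathrm{Poisson}$
with a log-rate loading on $z$ (mean matched analytically). The outcome is
Bernoulli with logit probability $\alpha + \sum_k\beta_k x_k$ on the
*recoded* determinants — the same recoding path the estimator uses — and
weights are uniform on [0.5, 1.5].

Defaults reproduce the benchmark's study conditions: wave sample sizes
7,532 and 10,864; covariate marginals at the published wave-specific
distributions; $\beta$ at the published log odds ratios; intercepts
−1.140 / 2.289, fixed once by a large-sample root-find so the waves land at
the published prevalences 0.304 and 0.829. The early wave is strongly
pro-rich (CI ≈ 0.27) and the late wave nearly equal (CI ≈ 0.04) — the
ordering and rough magnitudes of the benchmark, exercising the
prevalence-dependent bound that motivates the Erreygers index, though the
copula's single-factor wealth structure yields a somewhat smaller early-wave
CI than the published 0.507.

What the generator does *not* emulate: cluster/stratum sampling design
(weights are i.i.d., so design-based variance questions are out of reach),
item nonresponse, recall error, and any dependence between covariates
beyond what the shared wealth factor induces. Passing recovery tests
therefore show the estimating pipeline is consistent for its estimand under
a correctly specified single-factor process — not that real-survey biases
are handled.

**Ground-truth oracle.** `true_decomposition` evaluates the decomposition
target on a large simulated sample (default n = 200,000) with *no model
fitting*: marginal effects come from the true coefficients, the outcome
side uses the true probabilities (removing Bernoulli noise), and $C_k$ is
taken against the asset-PCA ranking of the large sample — the estimand of
the observable pipeline, which measures wealth through assets rather than
through the unobservable factor. This keeps the oracle independent of the
fitted-logit path it checks. The recovery test runs the full estimating
pipeline on a 50,000-row wave and requires agreement within 3 Monte-Carlo
standard errors, with the SE estimated from 25 disjoint subsamples (each
re-running the entire pipeline, so PCA and logit noise are included).

## Numerical choices

* Weighted covariance: population convention throughout (exactness of the
  identities beats unbiasedness here).
* Weights are normalized to the sample size before likelihood fitting;
  point estimates — the package's contract — are unaffected.
* Collinearity: the weighted design matrix is rank-checked before fitting;
  redundant columns are named via sequential projection. Coefficients above
  30 in absolute value after convergence are treated as separation and
  reported with the offending column.
* Tie handling: ranks use weighted-mean tie-group ranks; quintile blocks go
  to the lower quintile; both deterministic.
* PCA orientation fallback (no indicator given): positive correlation with
  the per-row asset count.
* Report rounding (CSV output only): 3 decimals for dy/dx, means, $C_k$,
  elasticities; 4 for shares; 1 for percent shares. JSON output is
  unrounded.

## Known limitations

* No standard errors or dominance tests for concentration indices, and no
  confidence intervals on contributions (bootstrap hooks are future work).
* The logit-AME decomposition's residual mixes the model residual with the
  linearization error; only the LPM gives a pure $GC_e/\mu$ residual.
* The wealth index is re-estimated per wave; cross-wave comparability of
  $C_k$ rests on the ranking, not on comparable score scales (ranks are
  invariant to monotone transforms, which is why the CI machinery only ever
  consumes ranks).
* Survey-design variance (clustering, stratification) is out of scope;
  weights enter point estimates only.
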