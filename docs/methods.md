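# Methods

## Scope and model

The package implements the prevalence-based (Sullivan) decomposition of
period life expectancy.  Three ingredients combine:

1. an abridged period life table per sex on the grid 60–64, 65–69, 70–74,
   75–79, 80+ (any strictly increasing grid with one open interval is
   accepted, including fine fractional grids used for validation);
2. age-group prevalence of a dichotomous "unhealthy" state from a
   cross-sectional survey;
3. the Sullivan identity `HLE_x = Σ_{i≥x}(1−π_i)L_i / l_x`, with
   `UHLE = e − HLE` and the proportion unhealthy `100·UHLE/e`.

The method assumes period mortality and current morbidity prevalence are
held fixed (a synthetic-cohort interpretation), that the survey prevalence
applies homogeneously within each age group (the 80+ survey estimate is
applied unchanged to the whole open interval), and that the mortality and
morbidity data sources are independent.  Incidence-based (multistate)
health expectancy is out of scope.

## Life tables (Chiang)

Closed intervals use `q = n·m / (1 + (n−a)·m)`; the open interval has
`q = 1` and `L = l/m`.  Defaults and rationale:

* `a = n/2` (2.5 years) for every closed interval.  Above age 60 the
  within-interval death distribution is close enough to uniform that the
  choice is immaterial at the reported precision; `a` is configurable per
  interval.
* Radix 100,000; every published identity is radix-invariant (tested).
* `var(q) = q²(1−q)/D`; cells with `D = 0` get `q = var(q) = 0` and a
  logged warning.  Extreme rates that would push `q` above 1 are clipped
  with a warning.
* `var(e_x) = Σ_{j≥x} l_j²[(n_j−a_j) + e_{j+1}]² var(q_j) / l_x²`, plus a
  terminal term `l_w² e_w² / D_w` from treating `e_w = 1/m_w` with
  Poisson-distributed deaths (delta method).  The terminal term is on by
  default and switchable off for a purely binomial treatment.
* Multi-year death counts are averaged arithmetically; the population is
  the single mid-period count.  Note that when a variance is wanted for a
  rate built from several years of deaths, the count actually observed
  (not the per-year average) is the right `D`; the coverage validation
  therefore simulates single-year registries.
* Confidence intervals use z = 1.96 throughout (95%).

Degenerate inputs: a terminal rate of zero while survivors still reach the
open group raises an error (the table cannot be closed); if nobody reaches
it, the terminal person-years are zero and expectancies are reported as 0.

## Health-state classification

Poor self-rated health is "fair" or "poor" on the five-level rating.  From
the four physical-functioning items (g: walking > 1 mile, h: several
hundred yards, i: one hundred yards, j: bathing/dressing):

* severe ⇔ i and/or j limited;
* mild/moderate ⇔ (g and/or h limited) and *neither* i nor j limited —
  the "neither" reading keeps the two grades mutually exclusive, which the
  additivity of the published prevalence tables confirms;
* global ⇔ any item limited, so global = mild/moderate + severe exactly.

Items may arrive dichotomous or on the 3-level scale ("limited a lot",
"limited a little", "not limited"); the latter maps both "limited" levels
to limited.  Missing responses propagate through Kleene logic (an observed
severe limitation classifies the respondent regardless of missing easier
items) and estimation is complete-case per indicator, with dropped counts
logged.  No imputation.

## Prevalence estimation

`π = Σwy/Σw` per sex × age-group cell.  Variance options:

* **Taylor** (default): with-replacement between-PSU linearization,
  `var = n_c/(n_c−1) Σ_c z_c²/W²` with PSU totals
  `z_c = Σ_{k∈c} w_k(y_k−π)`.  With every record its own PSU and equal
  weights this is the binomial variance times `n/(n−1)`.  A single-PSU
  cell falls back to the deff mode with a warning.
* **deff**: `var = deff₀·π(1−π)/n`, default `deff₀ = 2`, for data without
  PSU identifiers.

In Taylor mode the estimator also returns the full between-PSU covariance
matrix of the age-group prevalences.  Respondents of one census tract
appear in several age groups, so the group estimates are positively
correlated; ignoring that correlation understates the variance of any sum
over groups.  Validation on the default scenario: the diagonal-only HLE60
variance gave ~89% empirical coverage of a nominal 95% interval, while the
full-matrix version gave 94.2% (2,000 replicates; mean analytic variance
0.231 vs empirical 0.240).

Confidence intervals are linear-scale by default, truncated to [0,1]; a
logit-scale option exists.  Group differences in prevalence are tested by
a second-order (Satterthwaite) Rao–Scott adjusted Pearson chi-square on
the weighted table: the generalized design effects are the eigenvalues of
`V₀⁻¹V` on the contrast space, with `V` the linearized design covariance
and `V₀` its multinomial counterpart; the adjusted statistic is referred
to `F(d_s, d_s·(n_PSU−1))` with Satterthwaite degrees of freedom `d_s`.
The classical Pearson test on unweighted counts is available for
comparison.  The adjusted test's empirical type-I error under a clustered
null is validated at ~0.05 in the acceptance suite.

## Sullivan variances and comparisons

The default (`prevalence_only`) variance propagates only the prevalence
sampling variance,

`var(HLE_x) = Σ_{i,j≥x} L_i L_j cov(π_i, π_j) / l_x²`,

falling back to the diagonal form `Σ L_i² var(π_i) / l_x²` when no
covariance matrix is available (published prevalences, deff mode).  With
registered deaths numbering tens of thousands against a survey of ~1,500,
the mortality contribution is an order of magnitude smaller; a
`plus_mortality` mode nevertheless adds it by rerunning the Chiang
e-variance recursion on healthy person-years
(`l_j²[(n_j−a_j)(1−π_j) + HLE_{j+1}]² var(q_j)` per closed interval, with
the matching terminal term), treating the two sources as independent.
Under `prevalence_only`, `var(UHLE) = var(HLE)` by complement symmetry.

Sex differences in LE, HLE and UHLE use Wald intervals with summed
variances (independent sexes assumed); a difference is starred when its
95% interval excludes zero.  Proportions unhealthy are computed from
unrounded quantities and rounded (half-even, one decimal) only at render
time.

A useful analytic identity: at the open-ended exact age the proportion
unhealthy equals the terminal prevalence itself,
`100·UHLE(80)/e(80) = 100·π_{80+}`, for any life table — this is what the
acceptance script exploits.

## Synthetic-data generator

The generator's defaults describe the study conditions the package is
sized for: a large Brazilian city's population aged 60+ and its 2008
household health survey.

* **Mortality**: Gompertz hazards `α·exp(β(x−60))` with β = 0.09 and α
  calibrated once by root-finding on the integral survival so that true
  e60 ≈ 19.2 y (men, α = 0.0130) and 23.7 y (women, α = 0.0078) — the
  female advantage of ~4.5 years typical of this setting.  Closed-interval
  rates are taken at interval midpoints; the open interval uses
  `1/e(80)` from the integral so it is internally consistent.  The
  midpoint approximation biases abridged e60 by < 0.05 y over the
  realistic parameter range (checked against the integral oracle).
  Deaths are Poisson around `m_i·P_i` per year; populations default to
  ~60,000 men and ~74,000 women spread over the five groups.
* **Survey**: 50 PSUs × 30 respondents (≈ the real survey's 1,519).
  Sex-and-age-group cells are drawn with probabilities matching the
  published cell sizes; ages are uniform within closed groups and
  truncated-exponential (mean 4.5 y, capped at 100) in the open group.
  A latent three-level severity follows a proportional-odds model in age
  and sex with a shared normal PSU intercept; thresholds (-1.30 global,
  -3.13 severe at age 60 for men), slope 0.065/y and female offset 0.45
  were set once so group prevalences rise from ~24% to ~58% (men, global)
  and ~34% to ~69% (women), with severe limitation reaching ~18%/26% at
  80+ — the ranges a survey of this population reports.  Item responses
  are generated conditionally on severity so the classification rules
  recover it exactly (hence exact additivity of the grades).  Poor
  self-rated health uses a separate age-flat, sex-flat logistic model at
  ~12%, which doubles as a built-in null for the chi-square validation.
* **Clustering**: the latent-scale ICC default 0.034 sizes the
  whole-sample design effect near 2 at 30 respondents per PSU
  (`deff ≈ 1 + (m̄−1)ρ`); within single cells the effective cluster size,
  and hence the deff, is smaller.  Weights are constant by default with
  an optional lognormal spread.
* **Ground truth** integrates the closed-form Gompertz survival on a
  0.01-year mesh to age 110, marginalizes the PSU random effect by
  Gauss–Hermite quadrature (40 nodes), and averages prevalence over the
  within-group age densities; true HLE integrates `(1−π(x))·S(x)` with π
  step-constant on the grid.

What the generator does *not* emulate: non-response, proxy interviews,
institutionalized populations, post-stratified weights, or
probability-proportional-to-size PSU selection.  Passing validation
therefore shows the estimators are correct under a faithful idealization
of the design, not that any real survey meets those idealizations.

## Validation sizes and numerical choices

Simulation-based checks use 1,000 replicates at the default study scale
(coverage of the 95% intervals for prevalence, e60, HLE60 and the sex gap
in HLE60; chi-square type-I error), 250-replicate resampling oracles for
the Taylor and Sullivan variances, and a single large run (populations
×100, survey n = 100,000) for parameter recovery within 0.1 y.  These
sizes keep Monte-Carlo error a few times smaller than the tolerance being
asserted.  Conservation identities are checked to 1e-9 relative; the
fine-grid life-table oracle to 0.05 y.  Eigenvalues in the Rao–Scott
adjustment are floored at 1e-12; weighted Pearson terms with zero expected
proportion are dropped (they contribute no information).

## Known limitations

* The Jagger-style intervals ignore the survey/registry covariance (none
  exists by design here) and use z rather than t quantiles; with 50 PSUs
  the difference is under half a coverage point.
* `prevalence_only` intervals omit mortality noise; for small populations
  switch to `plus_mortality`.
* The chi-square F reference is asymptotic in the number of PSUs; with
  very few clusters (< ~20) its size has not been validated here.
* Prevalence at ages 60+ is assumed measured on the non-institutionalized
  population; no adjustment is attempted.
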