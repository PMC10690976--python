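# Methods

## Model and procedure

The analysis operates on one record per insured individual: a region code,
needs covariates X (age band, obesity, childbirth), preference covariates Z
(sex, SES category, income category, urbanization quartile), and two binary
outcomes — an initial specialist visit I and treatment T. Three stage
outcomes are modelled: Pr(T) and Pr(I) in the full population, and Pr(T|I)
among individuals with an initial visit.

Each stage is fitted by a maximum-likelihood logistic regression containing
a full set of region dummies (one region, the reference, absorbed into the
intercept) at three nested adjustment levels: crude (region only), needs-
adjusted (+X), and needs-and-preference-adjusted (+X+Z). Every covariate is
categorical with a documented reference category: age 0–40, non-obese, no
recent childbirth, male, high SES, high income, urbanization level 1.

**Sample selection.** Some treated individuals have no in-window visit
claim (their initial visit predates the observation window). They are
assumed to have had a visit: they enter the Pr(T) and Pr(T|I) samples with
`initial_visit = 1`, but are excluded from the Pr(I) sample, where their
visit status carries no in-window information. The conditional sample would
make any "had a visit" regressor constant, so the conditional models
instead carry a binary indicator separating *observed* from *assumed*
visits (coefficient π). It is on by default and dropped automatically
(with a warning) when the sample contains no censored visits.

**Standardization.** Predictions are computed per individual with X and Z
overridden by a single reference assignment (by default the model reference
categories, and an observed visit for the conditional stage), summed within
region and divided by the regional count. Because the covariates are fixed,
every individual in region *a* receives the identical value
`invlogit(b0 + b_a [+ theta'Xref + gamma'Zref + pi])`, and the regional
mean equals it. Two consequences worth being explicit about:

* the regional sums are divided by regional counts (probabilities), since
  the dispersion statistic below needs quantities whose mean is a mean
  probability — raw sums would conflate region size with rate;
* the choice of reference assignment shifts *all* regions by a common
  logit offset. It therefore changes the CVU level (the logit→probability
  map is nonlinear) but not the ranking of regions. The reference
  assignment is configurable and recorded with every output; comparisons
  should only ever be made between CVUs computed at the same assignment.

**Dispersion.** For each (stage, model) the CVU is the coefficient of
variation of the standardized regional probabilities: their SD divided by
their mean, unweighted across regions. The SD uses the sample (n−1)
denominator — regions are treated as draws from a dispersion process; a
population-weighted mean/SD is available off the default path.

**Inference.** The sampling distribution of each CVU comes from a
nonparametric bootstrap that resamples individuals with replacement,
re-applies the stage sample selections, refits every model, and recomputes
every standardized probability and CVU per replicate. All stages and
levels are computed on the *same* resample, so replicate-wise differences
are paired, and the three equality hypotheses — H1: CVU(T)=CVU(I), H2:
CVU(T|I)=CVU(I), H3: CVU(T)=CVU(T|I) — are tested from percentile
intervals of the per-replicate difference; the two-sided p-value is
`2·min(frac ≤ 0, frac ≥ 0)`, clipped to [0,1]. Both the bootstrap SD and
the percentile CI are reported. The default number of replicates is
10,000 (the reference procedure); the test-suite experiments use 300–500.

Resampling is stratified by region by default (resample within region,
preserving regional sample sizes) so that every region dummy remains
estimable in every replicate; simple unstratified resampling is available
by flag. Replicates in which a stage loses all events (or a model becomes
inestimable — a region or the visit indicator with no exposure, which can
happen unstratified) are excluded and counted; more than 5% exclusions is
a hard error. Per-replicate random streams are spawned from the master
seed by counter, so results are independent of execution order.

## Estimation engine

All covariates are categorical, so a table of any size collapses without
information loss onto covariate cells with (events, trials) counts. Models
are fitted by Newton–Raphson with step halving on the grouped binomial
likelihood — estimates, covariance (inverse observed information) and the
reported Bernoulli log-likelihood/AIC are identical to a row-level logistic
fit, which the test suite verifies against `statsmodels.Logit` to 1e-8.
The collapse is what makes full-refit bootstrapping cheap enough to run
hundreds of thousands of fits in the calibration experiments.

Numerical choices: convergence when the score's max-norm falls below
1e-8 × (number of observations); at most 100 iterations; iteration stops
early once any coefficient passes ±30 (fitted probabilities numerically
0/1). Quasi-separation — a dummy whose support carries zero events or only
events, e.g. a region with no cases — is detected explicitly; the
coefficient is retained (diverging, so the region's standardized
probability is numerically 0/1) and flagged rather than dropped, because
dropping a region would silently change the set of regions over which the
CVU is computed. Constant outcomes raise an error.

**Marginal effects.** For each non-reference level of each modelled
covariate, the average marginal effect is the sample mean of the discrete
change in predicted probability when the covariate is switched from its
reference level to that level, holding everything else at observed values;
standard errors are delta-method. (An at-means variant was considered and
rejected: with predominantly binary covariates the "mean individual" is
nobody.) Region dummies and the visit indicator are not tabulated.

## The synthetic generator

`stagevar.simulate` emulates a gatekept two-stage claims extract: regions
and covariates are drawn from configurable marginals (defaulting to the
descriptive margins of the motivating population: age bands
49.0/27.5/11.1/12.4%, half female, 2% recent childbirth, uniform
urbanization; obesity 0.002 — small but estimable; SES/income uniform, as
their margins are not reported); the initial visit is Bernoulli on
`invlogit(alpha_visit[region] + theta'X + gamma'Z)`; treatment is drawn
*only among visitors* (gatekeeping: treated ⇒ visited); and each treated
individual's visit record is censored with probability `p_censor_visit`
(default 5345/20453 ≈ 0.261, the observed share of treated patients with
no in-window visit claim). Untreated visit records are never censored.
Covariates are drawn independently of region by default so that
confounding can be switched on deliberately rather than lurking in every
test.

Because the DGP is logistic in exactly the analysis model's terms, the
true standardized regional probabilities are available in closed form —
`invlogit(alpha)` per stage at the reference assignment, their product for
the unconditional treatment stage — and `true_stage_cvus()` returns the
implied true CVUs. That makes parameter recovery well-posed by
construction; model misspecification is a scenario choice, not the
default. Note one deliberate misspecification that is always present: the
unconditional treatment model fits a logistic to a product of two
logistics. With region dummies this is harmless for the crude model
(saturated in region) and mild for the adjusted ones.

Two scenario factories define the study conditions used by the tests and
the acceptance script:

* `referral_dominated_params` — the qualitative regime of the motivating
  finding: low mean visit rate (0.05) with large log-scale regional spread
  (σ = 0.8, CVU(I) ≈ 0.76), high conditional treatment rate (0.6) with a
  small regional pattern (cv 0.15) *anti-correlated* with the visit
  pattern (regions with many referrals treat a smaller share), so that
  CVU(I) > CVU(T) > CVU(T|I); plus modest covariate effects (women and
  older individuals seek visits more; conditional treatment favours the
  young and the obese) to exercise the adjusted models.
* `equal_stage_dispersion_params` — a null scenario for calibration: both
  stages share the identical multiplicative regional pattern, so
  CVU(I) = CVU(T|I) exactly (default 0.2). Stage probabilities default to
  0.5, where binomial information is maximal and the sampling-noise
  inflation of the regional SD is small and symmetric across the two
  stages, and visit censoring is off so the visit-stage estimand is
  exactly the generator's visit probability under the null.

**What the generator does not emulate** — and hence what passing tests do
not show about real claims data: regional covariate composition
differences (unless configured), area-level covariates measured at the
region rather than the person, multi-year longitudinal structure, claim
prices, and any non-logistic outcome process. Recovery results here
certify the estimator under its own assumptions, not the assumptions.

## Simulation experiment design

The statistical acceptance tests run at sizes chosen to make their Monte
Carlo tolerances meaningful on a single CPU: saturated-model identity at
n = 20,000 / 20 regions; CVU recovery at n = 200,000 / 30 regions with a
500-replicate bootstrap (each stage's point CVU within 3 bootstrap SDs of
truth); qualitative ordering and all-hypotheses-rejected at n = 100,000 /
20 regions; type-I calibration of H2 over 200 simulation repeats of
n = 20,000 with 300 replicates each (rejection rate within 3 binomial SEs
of 5%); and percentile-interval coverage for CVU(I) over 100 repeats of
n = 50,000 with 500 replicates (within 3 binomial SEs of 95%).

The recovery experiment runs with censoring off and zero covariate
effects. This is not a simplification of convenience: excluding censored
treated records changes the visit-stage *estimand* itself — regions'
exclusion fractions differ through their treatment rates, measurably
inflating CVU(I) (about +6% in the default regime, where treatment rates
anti-correlate with visit rates) — so the closed-form truth is only the
correct oracle for the uncensored process. The selection behaviour of the
filtering rule is tested directly instead.

## Known limitations

* The CVU level depends on the standardization reference assignment (see
  above); no single "the" CVU exists without naming that assignment.
* CVU point estimates are biased upward in small samples (sampling noise
  adds to the between-region SD); the bootstrap quantifies spread around
  the estimate but does not remove that bias. With few events per region
  the conditional stage is affected first.
* Percentile intervals, not BCa/studentized; for strongly skewed CVU
  sampling distributions at small n their coverage can drift from nominal.
* Excluding censored treated individuals from the visit stage changes the
  visit-stage estimand whenever censoring correlates with region (see
  the recovery-experiment note); with regionally uniform censoring the
  distortion is a common factor and the CVU is nearly unaffected.
* Region effects are fixed effects; no shrinkage is applied, so very small
  regions contribute noisy standardized probabilities to the CVU.
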