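# Methods

## The model in brief

`ovafit` implements a two-stage quantitative description of how female
fertility potential changes with age, and turns it into a live-birth
prediction tool.

**Stage one — interpretable decline curves.** The live-birth rate per single
vitrified-warmed blastocyst transfer (SVBT), viewed as a function of
maternal age x, is modeled with a declining Verhulst-type logistic

    y(x) = y0 / (1 + exp((x − x0) / ω))

whose three parameters are directly meaningful: y0 is the maximum achievable
rate (an extrinsic parameter — it can move with laboratory technique), x0 is
the *half-peak age* at which the rate has fallen to y0/2, and ω is the
*decline width* setting how quickly the fall happens. x0 and ω are intrinsic
to oocyte quality: rescaling the outcome (for example analyzing euploidy
rate instead of live-birth rate) changes y0 only. From a fitted curve the
age at which the rate reaches any fraction f of its peak is available in
closed form, x0 + ω·ln(1/f − 1).

Ovarian reserve ("oocyte quantity") is described by four *quantifying
factors*: serum AMH (ng/mL), antral follicle count, mature oocyte count and
transferable embryo count per retrieval. Within an age group each factor is
right-skewed and well approximated by a gamma distribution. Instead of
fitting a separate gamma per age, the whole age-by-value surface is tied
together by six parameters: the age trajectories of the gamma's mean and
mode each follow the logistic decline above, and the gamma at age a is the
unique one with that mean and mode (scale θ = mean − mode, shape k =
mean/θ; valid whenever mean > mode > 0, i.e. k > 1). The fitted surface
yields reference percentile curves (a nomogram) at arbitrary quantiles even
though only the mean and mode are optimized.

**Stage two — scaled logistic regression.** Each continuous covariate is
mapped through its own stage-one fit of the marginal live-birth rate and
then through the logit: scaled = logit(ŷ(raw)/100), with ŷ clipped to
[0.1, 99.9]% first. This linearizes the covariate's relationship with the
outcome logit, so an ordinary logistic regression on scaled covariates
captures the nonlinear marginal effects. The per-transfer model uses age,
ordinal Gardner grade (AA=0; AB/BA=1; BB/AC=2; BC/CB=3; CA and CC excluded
for scarcity) and culture day (binary, day 6 = 1). The per-retrieval models
use age, one quantifying factor at a time (the four are mutually correlated
at r ≥ 0.7, so they never enter jointly) and retrieval-cycle index. With a
cycle covariate in the model, the cumulative live-birth rate over n cycles
is CLBR(n) = 1 − Π(1 − p_i), assuming cycles are independent given the
covariates — a stated model assumption, not a finding.

## Fitting machinery and numerical choices

* **WNLSR.** The weighted objective is Σ w_i (y_i − f(x_i; θ))² with
  w_i = n_i/Σn (weights normalized to sum to one; multiplying all n by a
  constant cannot change the fit). The solver is SciPy's bounded
  trust-region least squares with five deterministic multi-starts (the
  data-driven initialization plus four seeded perturbations), because the
  logistic fit is mildly non-convex in (x0, ω). Defaults: initialization
  y0 = max y, x0 = the x whose y is nearest y0/2, ω = 3 y; bounds
  y0 ∈ (0, 2·max y], x0 ∈ [20, 60] y, ω ∈ [0.1, 20] y. Convergence
  tolerances 1e-12.
* **Uncertainty.** Asymptotic t-based Wald intervals from the weighted
  Jacobian: cov = s²(JᵀWJ)⁻¹ with s² = SSE_w/(m − p), where m is the number
  of fitted points (ages), not Σn — points are the fitting units. Adjusted
  R² is computed about the weighted mean: 1 − (1 − R²)(m − 1)/(m − p − 1).
* **TWNLSR.** Per-age histograms (AMH binned at 0.25 ng/mL from zero;
  counts in unit bins with half-integer edges, the zero count kept in
  [0, 0.5) because zero-yield retrieval cycles are real data) are compared
  with the model's *bin-integrated* gamma probabilities (CDF differences),
  which is exact for counts and insensitive to bin width. Ages with fewer
  than 10 records are dropped. The six-parameter joint fit is initialized
  from separate logistic fits to the per-age histogram mean and
  histogram-argmax mode, solved as age-weighted least squares, and then
  polished by binned multinomial maximum likelihood (L-BFGS-B followed by
  Nelder–Mead). The polish matters: on simulated cohorts the plain
  equal-bin-weight least-squares estimator of the mean-curve maximum has
  roughly 1.5× the sampling spread of the ML estimate, and the ML estimate
  sits at the information bound for this design. CIs on the default path
  come from the observed Fisher information (numerical Hessian of the
  binned log-likelihood). Search-region violations of mean > mode > 0 are
  handled by clamping plus a penalty term; the returned surface is
  validated over its fitted age range.
* **Logistic regression.** Maximum likelihood via statsmodels (IRLS), Wald
  SEs/CIs, two-sided Wald p-values, aOR = exp(coefficient). Complete
  separation and collinear designs raise dedicated errors. Discrimination
  is summarized by the rank-statistic AUC; the "optimal threshold"
  maximizes Youden's J on the ROC, and accuracy is computed at that
  threshold (scikit-learn ROC utilities).
* **Scales.** Rates live on the percent scale (0–100) throughout the curve
  layer, matching the clinical reporting convention; probabilities appear
  only at the regression boundary.

## The synthetic cohort generator

No patient-level data ship with the package; the generator produces cohorts
with exactly the statistical structure the models assume, calibrated to the
published estimates:

* Per-age live-birth series: trials allocated over ages 27–45 by a
  clinic-like triangular profile peaking at age 38 over a 15% uniform base
  (largest-remainder rounding keeps the total exact; default Σn = 125,674,
  the registry scale), successes Binomial with rate from the quality curve
  (42.7%, 40.1 y, 3.02 y).
* Reserve cohorts: values drawn from the gamma surface (AMH mean curve
  6.5 ng/mL / 35.5 y / 5.7 y, mode curve 3.8 / 34.3 / 3.4, and analogous
  published parameters for the three count factors), default n = 5,638 for
  AMH and 2,698 for count factors, allocated by the same profile shape
  peaking at 36 (reserve testing skews slightly younger than transfer
  cycles); count factors rounded to non-negative integers.
* Per-transfer and per-retrieval outcome cohorts: covariates drawn
  *directly on the scaled scale* — Age_scaled ~ U(10, 45), Grade_scaled ~
  U(0, 3), culture day ~ Bernoulli(0.5), factor_scaled ~ U(0, 10), cycle ~
  U(1, 6) — and outcomes Bernoulli through the published logit equations.
  Sampling on the scaled scale makes printed-coefficient recovery
  well-posed without knowing the clinic's exact raw-to-scaled calibration.
* Retrieval trajectories: patients undergo successive cycles until live
  birth, a 6-cycle cap, or random censoring at per-cycle hazards matching
  the published exclusion tallies (14/4,181 spontaneous pregnancies,
  54/4,181 patient-related); censored cycles carry no outcome.

A single seed expands into named substreams, so adding a generator never
perturbs existing outputs, and identical configurations are byte-identical.

What the generator does *not* emulate: within-patient correlation of
repeated AMH measurements (records are independent, as in the source
analysis), patient-background covariates (BMI, stimulation protocol,
diagnosis), longitudinal AMH trajectories, assay or ethnicity differences,
and any model misspecification — real distributions are only approximately
gamma, real decline curves only approximately logistic. Passing recovery
tests therefore demonstrates correctness of the estimators under the
model's own assumptions, not the adequacy of those assumptions for any
particular clinic.

## Design decisions where the design was open

* **Logistic parameterization.** y0/(1 + exp((x − x0)/ω)) makes x0 the
  literal half-peak age and reproduces the published 75%- and 25%-of-peak
  ages (36.8 → 37 and 43.4 → 43). Known discrepancy: a symmetric logistic
  with these parameters puts the 90%/10%-of-peak ages at 33.5 and 46.7
  (rounding to 33 and 47), not the published 34 and 46; no symmetric
  logistic is consistent with all five published ages, so the quartile ages
  are the anchored checks and the 90%/10% values are not asserted.
* **"Cumulative probability" curve for factor-versus-rate.** Implemented as
  the two-parameter exponential-CDF form ymax(1 − e^(−x/τ)); a gamma-CDF
  variant is registered in the curve registry for configuration.
* **Scaling transform.** The exact transform behind the published
  coefficient magnitudes is not recoverable from the publication; the logit
  of the fitted marginal rate is used, with the documented consequence that
  refit coefficients on raw-shaped data need not numerically match the
  published equations, while models simulated *from* those equations are
  recovered exactly in distribution.
* **Threshold.** "Optimal threshold" is taken as Youden's J maximizer.
* **TWNLSR estimator.** The least-squares stage follows the declared
  objective; the ML polish (described above) is the package's default
  because it is markedly more efficient at clinic-scale n. See the
  limitation below.
* **AMH repeated measures** enter as independent records (5,638
  measurements on 4,972 individuals in the source data, no clustering
  adjustment stated).

## Problem sizes used in the checks

The recovery suites run 100 replicates at the study scales (Σn = 125,674
for the quality series; n = 5,638 for AMH). The acceptance script reports
each stochastic recovery as the mean recovered estimate over 5 independent
seeded replicates at those same scales, which reduces Monte-Carlo noise in
the single reported number; logit recoveries use n = 50,000 draws per
replicate.

## Known limitations

* At the AMH cohort scale (n ≈ 5,600, ages 27–45) the frequentist sampling
  spread of the surface's mean-curve parameters — even for the
  maximum-likelihood estimator, which attains the Cramér–Rao bound here
  (sd ≈ 0.45 ng/mL on the maximum, ≈ 0.9 y on the half-peak age) — is
  larger than the published CI half-widths (0.5 ng/mL, 1.0 y). Replicate
  recovered values therefore fall inside those intervals only ~75% of the
  time, not ≥90%: the published Wald intervals understate
  replicate-to-replicate variability of the design. The corresponding
  strict coverage test is retained and fails honestly.
* CLBR assumes cycle independence given covariates; real repeat cycles are
  selected (patients who succeed leave), so projected cumulative rates are
  model-based extrapolations.
* Wald intervals can be optimistic for strongly nonlinear parameters
  (notably y0, which extrapolates beyond the youngest observed age);
  bootstrap or profile-likelihood intervals are future work.
* The generators' age profiles are stylized; estimator precision in
  practice depends on the clinic's actual age mix.
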