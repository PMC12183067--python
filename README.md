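# ovafit

Two-stage statistical modeling of age-dependent oocyte **quality** and
**quantity**, and live-birth prediction built on top of it. The package is
aimed at reproductive-medicine researchers and biostatisticians who want
interpretable, parametric alternatives to polynomial or additive-model fits
of IVF outcome data — and a fully seeded synthetic clinic-cohort generator
for method validation when patient-level data cannot be shared.

## The models

**Oocyte quality.** The live-birth rate per single vitrified-warmed
blastocyst transfer declines with maternal age x following a Verhulst-type
logistic

```
y(x) = y0 / (1 + exp((x − x0) / ω))
```

with maximum rate y0 (%), half-peak age x0 (years) and decline width ω
(years). The curve is fitted by weighted nonlinear least squares (WNLSR),
each age weighted by its sample size. x0 and ω are intrinsic quality
parameters: rescaling the outcome (live birth vs euploidy rate) changes y0
only. The age at any fraction f of peak is x0 + ω·ln(1/f − 1).

**Oocyte quantity.** The within-age distribution of each ovarian-reserve
measure (AMH, antral follicle count, mature oocyte count, transferable
embryo count) is a gamma distribution whose mean and mode each follow a
logistic decline in age; the gamma at age a is the one with that mean m and
mode o (scale = m − o, shape = m/(m − o)). The six-parameter surface is
fitted to all per-age histograms at once (two-dimensional WNLSR with a
binned maximum-likelihood polish) and yields percentile nomograms at any
quantile.

**Live-birth prediction.** Logistic regressions on *scaled* covariates —
each continuous covariate passes through its own fitted marginal rate curve
and then the logit, linearizing its effect — model live birth per transfer
(age, Gardner grade group, culture day) and per retrieval cycle (age, one
reserve measure, cycle index). A cycle covariate turns per-cycle
predictions into cumulative live-birth rates, CLBR(n) = 1 − Π(1 − p_i).

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
import ovafit as ov

cfg = ov.CohortConfig(seed=1)                       # calibrated defaults
series = ov.generate_quality_series(cfg)            # per-age binomial series
fit = ov.fit_wnlsr(series, "logistic", seed=1)
print(fit.params, round(fit.r2_adj, 4))
for f in (0.75, 0.25):
    print(f, round(ov.percent_of_peak_age(fit.params, f), 1))
```

prints

```
LogisticDeclineParams(y0=43.051606981647, x0=39.97884476655846, omega=2.9974118675531636)
0.9968
0.75 36.7
0.25 43.3
```

i.e. from ~125,674 simulated transfer cycles the fit recovers the
generating curve (maximum 42.7%, half-peak age 40.1 y, width 3.02 y) almost
exactly, with adjusted R² ≈ 0.997, and the rate falls to 75% / 25% of peak
near ages 37 and 43. The reserve surface and nomogram:

```python
rec = ov.generate_reserve_cohort(cfg, "AMH")        # ~5,638 AMH draws
surf = ov.fit_twnlsr(ov.build_age_histograms(rec, "AMH", bin_width=0.25), seed=1)
print(ov.percentile_curves(surf, [30.0, 38.0, 44.0]).round(2))
```

```
 age   p5  p25  median  p75   p95  mean  mode
30.0 1.21 2.64    4.15 6.16 10.03  4.69  3.03
38.0 0.34 1.10    2.08 3.54  6.62  2.60  0.97
44.0 0.09 0.39    0.87 1.63  3.33  1.18  0.18
```

— the fitted median AMH halves between ages 30 and 38 and the whole
distribution narrows, exactly the nomogram a clinician would read ranges
from. Per-retrieval prediction and cumulative rates:

```python
df = ov.generate_opu_scaled_cohort(cfg, "AMH", n=50_000)
X = df[["age_scaled", "factor_scaled", "cycle_scaled"]]
model = ov.evaluate_model(ov.fit_logit(X, df["live_birth"]), X, df["live_birth"])
print(model.coef.round(3), round(model.auc, 3))
ov.cumulative_live_birth(model, {"age_scaled": 30.0, "factor_scaled": 1.0},
                         4, cycle_var="cycle_scaled")
```

recovers the generating coefficients (4.94, −0.159, 0.292, −0.190 vs the
calibration 4.922, −0.158, 0.286, −0.185; AUC 0.86) and projects CLBR
0.571 → 0.795 → 0.893 → 0.939 over four cycles for that covariate profile.

## Command line

```
ovafit --seed 3 simulate quality --out sim/
ovafit --seed 3 fit-quality  --input sim/quality.csv --out fit.csv
ovafit --seed 3 simulate reserve --factor AMH --out sim/
ovafit --seed 3 fit-quantity --input sim/reserve.csv --factor AMH \
       --out surface.csv --percentiles nomogram.csv
ovafit fit-svbt --input transfers.csv --out svbt.csv
ovafit fit-opu  --input retrievals.csv --factor AMH --out opu.csv
ovafit predict --model opu.csv --at age=2.1,factor_value=1.0,cycle=1
ovafit clbr    --model opu.csv --at age=2.1,factor_value=1.0 --cycles 6
```

Input schemas are plain CSV (`x,y,n` or `x,outcome` for rate series;
`age,value` for reserve records; `age,gardner,culture_day,live_birth` per
transfer; `age,cycle_index,factor_value,live_birth,censored_reason` per
retrieval). Exit codes: 0 success, 2 data error, 3 convergence error; every
run writes a `run_log.json` with the seed and config hash.

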