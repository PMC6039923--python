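# msalimit

Maximum-survivable-age estimation from life tables, with diagnostics for
the data artifacts — integer rounding, log(0)-as-log(1) regression, the
110-year age cap, and population pooling — that can manufacture spurious
"limits" to human lifespan.

## The problem

Claims that human lifespan is capped (e.g. that the maximum reported age
at death is limited to ~125 years) rest on analyses of published life
tables and supercentenarian record databases. Both data sources have
structural quirks: published life tables report survivors l_x as whole
counts out of a radix of 100,000 and truncate at age 110, and record
databases open and close their per-country validation coverage over
calendar time. An analysis that ignores these quirks — in particular one
that feeds zero-rounded survivorship into log-linear regressions as
log(0) = log(1), or pools record databases across moving coverage
windows — produces plateaus and declines that are properties of the data
handling, not of human mortality.

`msalimit` is for demographers and biostatisticians who want to (a)
estimate the age ceiling implied by log-linear mortality growth and (b)
reproduce, quantify, and correct each of these artifacts on fully
synthetic, seeded ground truth.

## The estimator

Adult human mortality is approximately Gompertzian: the hazard grows as
h(x) = a·e^{bx}, so the age-specific probability of death q_x is close
to log-linear in age. The model is

    log q_x = α + β·x + ε,      fitted by OLS over an age window,

and the **maximum survivable age (MSA)** is the projection to q = 1:

    MSA = −α/β,

with a 95% CI from the delta method on the coefficient ratio,
var(MSA) ≈ (1/β²)[se_α² + MSA²·se_β² + 2·MSA·cov_{αβ}]. On exactly
log-linear mortality MSA recovers −ln(a)/b exactly; the projection is
conservative in that it assumes no late-life mortality deceleration.

The package is organised statsmodels-style: `LogLinearMortality` is the
model, `fit()` returns an `MSAResults` with coefficients, covariance,
R², the MSA and its CI, and a `summary()`.

## Worked example

```python
from msalimit import GompertzParams, LogLinearMortality, make_gompertz_lifetable

params = GompertzParams(a=3e-5, b=0.1)          # realistic adult mortality
lt = make_gompertz_lifetable(params, max_age=110)
res = LogLinearMortality.from_lifetable(lt, age_window=(40, 95)).fit()
print(res.summary())
```

prints

```
Log-linear mortality model: log(qx) ~ age
  population: synthetic  year: 0
  age window: 40-95  ages used: 56  zero policy: drop
  intercept:   -10.221617  (se 0.01643)
  slope:         0.097319  (se 0.0002368)
  R^2:           0.999681
  MSA:         105.0318 years  95% CI [104.8370, 105.2267]
```

The fitted slope (0.0973) sits just below the true log-hazard slope
b = 0.1 because interval death probabilities bend slightly below the
hazard line; the projected limit of 105.0 years is within a year of the
age at which the underlying hazard itself reaches 1 (−ln(a)/b = 104.1),
and R² ≈ 0.9997 shows how well log-linearity approximates integrated
Gompertz mortality over adult ages.

The three artifact experiments run from one seeded pipeline:

```
msalimit run --experiment full --seed 3 --out run1
```

```
[rounding artifact]
  gain-rate slope at age 105 (exact lx, drop zeros):      +0.11854 / yr
  gain-rate slope at age 105 (rounded lx, log(0)=log(1)): -0.13843 / yr
  ...
[pooling artifact]
  pooled post-breakpoint MRAD slope:      -0.0712 yr/yr
     BIG post-breakpoint MRAD slope:      +0.0200 yr/yr
   SMALL post-breakpoint MRAD slope:      -0.0178 yr/yr
[msa trend]
  median fit R^2: 0.9996
  MSA first->last year: 100.62 -> 108.59 years
```

Read top to bottom: genuine old-age survival gains (+0.119/yr) flip sign
under rounding plus the log(0)=log(1) policy; a pooled record panel
shows a falling extreme age after the big country leaves coverage even
though neither country's own mortality worsened; and under steady 1%/yr
mortality improvement the survivable-age ceiling rises — it is a moving
quantity, not a constant of nature.

Real 1×1 life tables and record CSVs can be supplied in place of the
synthetic generators (`read_hmd_lifetable`, `read_death_records`); with
full historical data the same pipeline reproduces median fit R² ≈ 0.99
across population-years, a majority of zero-rounded l_x cells above age
90, and historic MSA values above 125 years.

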