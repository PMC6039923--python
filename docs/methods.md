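# Methods

## Mortality model

The generators and the estimator are both built on the Gompertz–Makeham
hazard

    h(x) = a·e^{bx} + c,        a > 0, b > 0, c ≥ 0,

with cumulative hazard H(x) = (a/b)(e^{bx} − 1) + c·x and survival
S(x) = e^{−H(x)}. Default parameter neighbourhoods (a ~ 3·10⁻⁵–8·10⁻⁵,
b ~ 0.10–0.11, c = 0) put adult mortality doubling times at 6–7 years
and survival to age 100 in the 10⁻³–10⁻⁵ range per birth, which is the
regime of 19th–20th century national life tables and the regime in which
integer rounding of l_x on a 100,000 radix starts destroying
information.

Two discrete q-constructions are deliberately kept side by side:

* **exactly log-linear**: q_x = min(1, a·e^{bx}). Here log q_x is a
  perfect line, so the estimator's exactness, window-invariance and
  monotonicity are provable and tested to 1e−9.
* **hazard-integrated**: q_x = 1 − exp(−[H(x+1) − H(x)]). This is the
  realistic generator; its log q_x bends slightly below the hazard line
  (1 − e^{−H} ≤ H), which is why fitted slopes sit just under b and
  projections land about a year above the hazard's unit crossing.

For hazard-integrated tables l_x is computed directly as radix·S(x)
rather than by chaining l_{x+1} = l_x(1 − q_x): past roughly age 115 the
interval hazard exceeds ~36 and 1 − e^{−H} rounds to exactly 1.0 in
double precision, so chaining would inject artificial exact zeros into
nominally exact tables. Direct evaluation keeps l_x positive wherever
H < ~745 while still satisfying the recursion to 1e−12 relative. For the
log-linear construction the recursion *is* the definition, since q
saturates at 1 there by design and the cohort closes out inside the
table.

## The estimator

`LogLinearMortality` fits log q_x = α + β·x by unweighted OLS over an
age window, excluding the terminal open interval, all ages with
q_x ≥ 1, and handling q_x = 0 by an explicit policy. The maximum
survivable age is MSA = −α/β, and its variance by the delta method is
(1/β²)(se_α² + MSA²·se_β² + 2·MSA·cov_{αβ}); the 95% CI is ±1.96 SE and
is symmetric, so it always contains the point estimate. A fitted β ≤ 0
raises a typed `NonProjectableFitError` — batch series record such fits
as absences with their reason rather than fabricating a limit.

Choices worth stating:

* **q_x, not m_x**: the probability of death is modelled directly; no
  central-rate conversion is involved.
* **Default window 40–95 years**: below ~40 the infant and early-adult
  mortality humps break log-linearity; above ~95 the zero-rounded cells
  of published tables concentrate. The window is a parameter and is
  always carried in the results; on real data MSA is window-sensitive
  and the reported window is part of the estimate.
* **Delta-method CI** rather than a prediction-band crossing: it is the
  standard first-order interval for a coefficient ratio, and its actual
  coverage is measured by simulation (96% at the default study size)
  rather than assumed.
* **Unweighted OLS**, classical t-based two-sided p-values, no
  multiple-testing correction — matching the conventional treatment of
  such regressions.

## Zero policies and the rounding diagnostic

`log_survival` makes the handling of zeros a first-class, named choice:
`drop` removes them and returns an index map of what was kept, `as_one`
substitutes log(0) → 0 (i.e. log(1)) and exists solely to reproduce the
artifact that substitution creates, and `fail` raises. The index map is
mandatory so downstream fits can report how many points each policy
discarded. Rounding error is quantified on the survivor-count scale
(rounded − exact, bounded by ±0.5), never the log scale, which is
undefined at zero. Integer rounding uses ties-away-from-zero by default
(half-even is available); survivor counts are positive so the two differ
only at exact .5 ties.

## Trend machinery

Annual survival gain rates are OLS slopes of log(l_x/radix) on calendar
year at a fixed age; the age of greatest gain is the argmax of that
slope over candidate ages, ties broken toward the older age, and
candidate ages missing from the tables (e.g. above a cap) are skipped —
which is exactly how an age cap pins the apparent gain peak to the cap.
Extreme-age series take the k-th largest recorded age per death year
(rank ties are stable by record id and occupy consecutive ranks); years
with fewer than k records are omitted. Segmented trends fit the two
sides of a fixed breakpoint independently and report a side with fewer
than three points as absent. `mse` in trend fits is the mean of squared
residuals (SSE/n). LOWESS is degree-1 local regression with tricube
weights over the span-nearest neighbours and bisquare robustness
iterations (defaults span 0.67, 3 iterations — the conventional
choices); statsmodels' implementation stands behind it and is pinned in
the tests against a closed-form tricube-weighted least-squares oracle at
interior points and against exact-line reproduction.

## What the synthetic data emulate — and what they do not

The generators reproduce the statistical structure the analyses assume:
Gompertz mortality with multiplicative secular decline in a (b fixed —
the simplest mechanism that raises −ln(a)/b linearly in time),
radix-100,000 cohorts with integer-rounded l_x, the 110-year terminal
cap, and record panels that are Poisson incidence processes over
per-country coverage windows with left-truncated Gompertz ages and
uniform death months (a fixed-count mode exists for variance-controlled
tests). They do **not** include Makeham background mortality in sampled
records, frailty heterogeneity, late-life mortality deceleration
(logistic/Kannisto), cohort–period interactions, or seasonality of
deaths. Passing tests therefore demonstrate that the pipeline measures
what it claims on data satisfying the Gompertz assumptions; they do not
by themselves validate log-linearity as a description of real late-life
human mortality, which is a substantive scientific assumption the
estimator states rather than tests.

## Simulation studies (desk scale)

The five studies in `msalimit.studies` are sized to run in seconds while
leaving the qualitative conclusions far from their decision boundaries:

* **Parameter recovery** — 50 cohorts of 100,000 deaths sampled
  multinomially from the exactly log-linear table (a = 3·10⁻⁵, b = 0.1),
  empirical life tables rebuilt from the deaths and refitted. Sampling
  from the log-linear table (not the continuous hazard) makes b the true
  slope of the estimand, so slope and MSA recovery and CI coverage are
  interpretable as pure finite-sample behaviour.
* **Rounding attenuation** — 20 replicates of a 1900–1990 improving
  series (1%/yr decline in a; a0 log-uniform in [5·10⁻⁵, 8·10⁻⁵], b
  uniform in [0.10, 0.11]), gain rate at age 105 compared between
  {exact l_x, drop} and {rounded l_x, as_one}. The parameter band is
  chosen so early-century survival to 105 rounds to zero while
  late-century survival does not — the crossing that makes the artifact
  bite.
* **Cap artifact** — same replicate scheme to age 120; capped tables pin
  the gain-rate argmax to 110 while uncapped tables place it above.
* **Pooling artifact** — 200 seeded panels of two countries with
  identical, time-constant mortality: BIG (25 expected records/yr,
  covered 1980–2003) and SMALL (2/yr, 1980–2010). The pooled post-1995
  extreme-age slope is negative in ~100% of seeds purely because of the
  2003 coverage loss. With constant per-country conditions each
  country's own post-1995 slope has expectation exactly zero, so its
  Monte-Carlo mean is checked against ±2 standard errors rather than
  against a literal sign.
* **Extreme-value monotonicity** — E[annual maximum age] across annual
  counts 10/100/1000 with common random numbers (the count-k maximum is
  the maximum over the first k of one shared draw), making the
  per-replicate maxima monotone by construction and the mean comparison
  noise-free.

## Degenerate inputs and numerical conventions

Constant annual series return slope 0 with r = 0 and p = 1 (avoiding
0/0 in the correlation). A flat gain-rate profile reports its argmax
with an explicit degenerate-maximum warning. LOWESS spans covering fewer
than two points are widened to two with a warning. File parsing treats
"." as a missing value that propagates as NaN — a missing cell never
becomes a numeric zero, since silently zeroed survivorship is precisely
the failure mode the rounding diagnostics exist to expose. Text
round-trips write floats at 17 significant digits and parse them with
correctly-rounded conversion, so write∘read is the identity on exact
tables.

## Known limitations

MSA is a population-schedule summary, not an individual prediction, and
inherits the window-sensitivity of the fit on real data. The delta
method is first-order and its CI can undercover for short windows or
very noisy empirical q_x. The record simulator draws ages from the pure
Gompertz tail above the threshold; real validated-record age
distributions carry validation-intensity and reporting effects the
panel model does not attempt.
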