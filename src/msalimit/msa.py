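"""Maximum survivable age (MSA) estimation.

The estimator: human adult mortality roughly doubles with age, so the
age-specific probability of death q_x is close to log-linear in age.
Ordinary least squares on log(q_x) ~ age, projected to log(q) = 0
(q = 1), gives the age past which survival is impossible under the
fitted schedule — the maximum survivable age

    MSA = -intercept / slope.

The projection is a conservative lower bound on any lifespan limit: it
assumes no late-life deceleration in mortality, which if present would
only raise the limit.  A 95% CI comes from the delta method on the
coefficient ratio,

    var(MSA) ~ (1/slope^2) * [se_int^2 + MSA^2*se_slope^2 + 2*MSA*cov],

with cov the slope-intercept covariance.

The module is organised statsmodels-style: :class:`LogLinearMortality`
is the model, built from a :class:`~msalimit.lifetable.LifeTable` (or raw
age/qx arrays); ``fit()`` returns :class:`MSAResults`, which carries the
coefficients, their covariance, R², the MSA with its CI, and a
``summary()`` table.  Thin functional wrappers (`fit_loglinear_mortality`,
`msa_from_fit`, `msa_series`, `check_records_against_msa`) cover batch
and record-validation use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import InsufficientDataError, NonProjectableFitError, ValidationError
from .lifetable import DeathRecord, LifeTable
from .rounding import log_survival

DEFAULT_AGE_WINDOW = (40, 95)


@dataclass(frozen=True)
class LogLinearFit:
    """Coefficients of the OLS fit of log(qx) on age."""

    intercept: float  # log(q) at age 0
    slope: float  # per-year increase in log(q)
    r2: float
    se_slope: float
    se_intercept: float
    cov_si: float  # slope-intercept covariance
    n_ages: int
    age_window: tuple[int, int]


@dataclass(frozen=True)
class MSAEstimate:
    """MSA for one population-year, with delta-method 95% CI."""

    population_id: str | None
    index_year: int | None
    msa: float
    ci95: tuple[float, float]
    fit: LogLinearFit


class LogLinearMortality:
    """Log-linear model of age-specific death probability.

    Parameters
    ----------
    ages, qx : array-like
        Age grid and death probabilities.  Ages outside ``age_window``,
        the terminal open interval, and ages with qx >= 1 are excluded
        from the fit; qx == 0 is handled by ``zero_policy`` ("drop",
        "as_one" or "fail" — see :func:`msalimit.rounding.log_survival`).
    age_window : (int, int)
        Inclusive fitting window.  The default 40–95 avoids the infant
        and early-adult mortality humps below and the zero-rounding
        regime of published tables above; it is always reported with the
        fit.
    """

    def __init__(
        self,
        ages,
        qx,
        age_window: tuple[int, int] = DEFAULT_AGE_WINDOW,
        zero_policy: str = "drop",
        population_id: str | None = None,
        index_year: int | None = None,
        terminal_open: bool = False,
    ):
        self.ages = np.asarray(ages, float)
        self.qx = np.asarray(qx, float)
        if self.ages.size != self.qx.size:
            raise ValidationError("ages and qx must have equal length")
        self.age_window = (int(age_window[0]), int(age_window[1]))
        self.zero_policy = zero_policy
        self.population_id = population_id
        self.index_year = index_year
        self.terminal_open = terminal_open

    @classmethod
    def from_lifetable(
        cls,
        lt: LifeTable,
        age_window: tuple[int, int] = DEFAULT_AGE_WINDOW,
        zero_policy: str = "drop",
    ) -> "LogLinearMortality":
        return cls(
            lt.ages,
            lt.qx,
            age_window=age_window,
            zero_policy=zero_policy,
            population_id=lt.population_id,
            index_year=lt.index_year,
            terminal_open=lt.open_interval,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, age_col: str = "age", qx_col: str = "qx", **kwargs
    ) -> "LogLinearMortality":
        return cls(df[age_col].to_numpy(), df[qx_col].to_numpy(), **kwargs)

    def _design(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.age_window
        keep = (self.ages >= lo) & (self.ages <= hi) & np.isfinite(self.qx)
        if self.terminal_open:
            keep[-1] = False
        keep &= self.qx < 1.0  # saturated q carries no log-linear information
        ages, q = self.ages[keep], self.qx[keep]
        logq, kept = log_survival(q, self.zero_policy)
        return ages[kept], logq

    def fit(self, require_projectable: bool = True) -> "MSAResults":
        """Fit by OLS.  With ``require_projectable`` (default) a slope <= 0
        raises :class:`NonProjectableFitError` — mortality that does not
        increase with age admits no finite survivable-age projection."""
        ages, logq = self._design()
        if ages.size < 3:
            raise InsufficientDataError(
                f"only {ages.size} usable ages in window {self.age_window}"
            )
        X = sm.add_constant(ages)
        res = sm.OLS(logq, X).fit()
        out = MSAResults(self, res, ages)
        if require_projectable and out.slope <= 0:
            raise NonProjectableFitError(
                f"fitted slope {out.slope:.4g} <= 0 for "
                f"{self.population_id}/{self.index_year}: mortality is not "
                "increasing over the window, MSA undefined"
            )
        return out


class MSAResults:
    """Results of a :class:`LogLinearMortality` fit."""

    def __init__(self, model: LogLinearMortality, ols_results, ages_used: np.ndarray):
        self.model = model
        self._ols = ols_results
        self.ages_used = ages_used
        self.intercept = float(ols_results.params[0])
        self.slope = float(ols_results.params[1])
        cov = np.asarray(ols_results.cov_params())
        self.se_intercept = float(math.sqrt(max(cov[0, 0], 0.0)))
        self.se_slope = float(math.sqrt(max(cov[1, 1], 0.0)))
        self.cov_si = float(cov[0, 1])
        self.r2 = float(ols_results.rsquared)
        self.nobs = int(ols_results.nobs)

    # -- projection -------------------------------------------------------
    @property
    def msa(self) -> float:
        """Age at which the fitted log(q) line crosses 0 (q = 1)."""
        if self.slope <= 0:
            raise NonProjectableFitError("slope <= 0: MSA undefined")
        return -self.intercept / self.slope

    @property
    def msa_se(self) -> float:
        m = self.msa
        var = (1.0 / self.slope**2) * (
            self.se_intercept**2 + m**2 * self.se_slope**2 + 2.0 * m * self.cov_si
        )
        return math.sqrt(max(var, 0.0))

    @property
    def msa_ci95(self) -> tuple[float, float]:
        m, se = self.msa, self.msa_se
        return (m - 1.96 * se, m + 1.96 * se)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self._ols.fittedvalues)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._ols.resid)

    def predict_logq(self, ages) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(ages, float)

    def as_loglinear_fit(self) -> LogLinearFit:
        return LogLinearFit(
            intercept=self.intercept,
            slope=self.slope,
            r2=self.r2,
            se_slope=self.se_slope,
            se_intercept=self.se_intercept,
            cov_si=self.cov_si,
            n_ages=self.nobs,
            age_window=self.model.age_window,
        )

    def as_estimate(self) -> MSAEstimate:
        return MSAEstimate(
            population_id=self.model.population_id,
            index_year=self.model.index_year,
            msa=self.msa,
            ci95=self.msa_ci95,
            fit=self.as_loglinear_fit(),
        )

    def summary(self) -> str:
        lines = [
            "Log-linear mortality model: log(qx) ~ age",
            f"  population: {self.model.population_id}  year: {self.model.index_year}",
            f"  age window: {self.model.age_window[0]}-{self.model.age_window[1]}"
            f"  ages used: {self.nobs}  zero policy: {self.model.zero_policy}",
            f"  intercept: {self.intercept:12.6f}  (se {self.se_intercept:.4g})",
            f"  slope:     {self.slope:12.6f}  (se {self.se_slope:.4g})",
            f"  R^2:       {self.r2:12.6f}",
        ]
        try:
            lo, hi = self.msa_ci95
            lines.append(f"  MSA:       {self.msa:10.4f} years  95% CI [{lo:.4f}, {hi:.4f}]")
        except NonProjectableFitError:
            lines.append("  MSA:       undefined (slope <= 0)")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Observed log(qx) and the fitted projection to q = 1."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ages, logq = self.model._design()
        ax.scatter(ages, logq, s=12, label="log qx")
        grid = np.linspace(ages.min(), self.msa if self.slope > 0 else ages.max(), 200)
        ax.plot(grid, self.predict_logq(grid), color="k", label="log-linear fit")
        ax.axhline(0.0, color="grey", lw=0.8, ls=":")
        ax.set_xlabel("age (years)")
        ax.set_ylabel("log q")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def fit_loglinear_mortality(
    lt: LifeTable,
    age_window: tuple[int, int] = DEFAULT_AGE_WINDOW,
    zero_policy: str = "drop",
) -> LogLinearFit:
    """OLS of log(qx) on age for one life table (raises if slope <= 0)."""
    return (
        LogLinearMortality.from_lifetable(lt, age_window, zero_policy)
        .fit()
        .as_loglinear_fit()
    )


def msa_from_fit(fit: LogLinearFit) -> MSAEstimate:
    """Project a fitted log-linear schedule to q = 1.

    Returns an :class:`MSAEstimate` (population fields unset) with the
    delta-method 95% CI.
    """
    if fit.slope <= 0:
        raise NonProjectableFitError("slope <= 0: MSA undefined")
    msa = -fit.intercept / fit.slope
    var = (1.0 / fit.slope**2) * (
        fit.se_intercept**2 + msa**2 * fit.se_slope**2 + 2.0 * msa * fit.cov_si
    )
    se = math.sqrt(max(var, 0.0))
    return MSAEstimate(None, None, msa, (msa - 1.96 * se, msa + 1.96 * se), fit)


@dataclass
class MSASeries:
    """MSA estimates over a table collection, with typed absences."""

    estimates: list[MSAEstimate]
    failures: list[tuple[str | None, int | None, str]]  # (population, year, reason)

    @property
    def median_r2(self) -> float:
        if not self.estimates:
            return float("nan")
        return float(np.median([e.fit.r2 for e in self.estimates]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "population": e.population_id,
                "year": e.index_year,
                "msa": e.msa,
                "ci_low": e.ci95[0],
                "ci_high": e.ci95[1],
                "slope": e.fit.slope,
                "intercept": e.fit.intercept,
                "r2": e.fit.r2,
                "n_ages": e.fit.n_ages,
                "status": "ok",
            }
            for e in self.estimates
        ]
        rows += [
            {"population": p, "year": y, "msa": np.nan, "ci_low": np.nan,
             "ci_high": np.nan, "slope": np.nan, "intercept": np.nan, "r2": np.nan,
             "n_ages": 0, "status": reason}
            for p, y, reason in self.failures
        ]
        return pd.DataFrame(rows).sort_values(["population", "year"]).reset_index(drop=True)


def msa_series(
    tables: Sequence[LifeTable],
    age_window: tuple[int, int] = DEFAULT_AGE_WINDOW,
    zero_policy: str = "drop",
) -> MSASeries:
    """One MSA estimate per population-year.  Non-projectable or
    data-starved fits are recorded as typed absences with their reason,
    never silently dropped — over noisy data a series must not fabricate
    limits from fits that carry none."""
    estimates, failures = [], []
    for lt in tables:
        try:
            res = LogLinearMortality.from_lifetable(lt, age_window, zero_policy).fit()
            estimates.append(res.as_estimate())
        except (NonProjectableFitError, InsufficientDataError) as exc:
            failures.append((lt.population_id, lt.index_year, f"{type(exc).__name__}: {exc}"))
    return MSASeries(estimates, failures)


# ---------------------------------------------------------------------------
# record validation against estimated limits
# ---------------------------------------------------------------------------

@dataclass
class MSACheck:
    """Comparison of observed record ages against estimated limits."""

    n_within: int
    n_exceeding: int
    margins: pd.DataFrame  # record_id, age, matched msa, margin = msa - age
    unmatched: list[str]


def check_records_against_msa(
    records: Sequence[DeathRecord],
    estimates: Sequence[MSAEstimate],
    matching: str = "death_year",
    by_country: bool = False,
) -> MSACheck:
    """Count records that exceed their matched MSA.

    Matching policies:
      death_year  — a record matches the estimate (period table) of its
                    year of death;
      birth_cohort — a record matches the estimate (cohort table) of its
                    birth year, death_year - floor(age).
    With ``by_country`` the match also requires population_id == country;
    otherwise estimates are treated as pooled.  Records with no matching
    estimate are reported as unmatched, never dropped.
    """
    if matching not in ("death_year", "birth_cohort"):
        raise ValidationError(f"unknown matching policy {matching!r}")
    index: dict = {}
    for e in estimates:
        key = (e.population_id, e.index_year) if by_country else e.index_year
        index[key] = e

    rows, unmatched = [], []
    for r in records:
        year = r.death_year if matching == "death_year" else r.death_year - int(r.age_at_death)
        key = (r.country, year) if by_country else year
        est = index.get(key)
        if est is None:
            unmatched.append(r.record_id)
            continue
        rows.append(
            {
                "record_id": r.record_id,
                "age_at_death": r.age_at_death,
                "msa": est.msa,
                "margin": est.msa - r.age_at_death,
            }
        )
    margins = pd.DataFrame(rows, columns=["record_id", "age_at_death", "msa", "margin"])
    exceeding = int((margins["margin"] < 0).sum()) if len(margins) else 0
    return MSACheck(
        n_within=len(margins) - exceeding,
        n_exceeding=exceeding,
        margins=margins,
        unmatched=unmatched,
    )
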