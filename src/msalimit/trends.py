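"""Calendar-time trend analyses: late-life survival gain rates, extreme
and mean reported ages at death, segmented linear trends, LOWESS
smoothing, and record filtering.

These are the tools with which the package separates genuine mortality
trends from three artifacts: log(0)-as-log(1) regression on rounded
survivorship, the 110-year cap on published tables, and pooling of record
databases whose per-country coverage windows open and close.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .exceptions import InsufficientDataError, ParameterError, ValidationError
from .lifetable import DeathRecord, LifeTable
from .rounding import log_survival


@dataclass
class AnnualSeries:
    """An annual time series: strictly increasing years, finite values."""

    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, int)
        self.values = np.asarray(self.values, float)
        if self.years.size != self.values.size:
            raise ValidationError("years and values must have equal length")
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise ValidationError("years must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values must be finite")

    def __len__(self) -> int:
        return self.years.size

    def window(self, window: tuple[int, int] | None) -> "AnnualSeries":
        if window is None:
            return AnnualSeries(self.years.copy(), self.values.copy())
        lo, hi = window
        keep = (self.years >= lo) & (self.years <= hi)
        return AnnualSeries(self.years[keep], self.values[keep])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of an annual series on calendar year.

    ``p_value`` is the classical two-sided test on the slope (t with n-2
    degrees of freedom); ``mse`` is the mean of squared residuals (SSE/n).
    """

    slope: float
    intercept: float
    r: float
    p_value: float
    mse: float
    n: int
    window: tuple[int, int]

    def predict(self, years) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(years, float)


def _ols_trend(years: np.ndarray, values: np.ndarray) -> TrendFit:
    n = years.size
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points for a trend, have {n}")
    if np.ptp(values) == 0:  # constant series: slope 0, no correlation
        return TrendFit(0.0, float(values[0]), 0.0, 1.0, 0.0, n, (int(years[0]), int(years[-1])))
    res = stats.linregress(years.astype(float), values)
    resid = values - (res.intercept + res.slope * years)
    return TrendFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_value=float(res.pvalue),
        mse=float(np.mean(resid**2)),
        n=n,
        window=(int(years[0]), int(years[-1])),
    )


def linear_trend(
    series: AnnualSeries,
    window: tuple[int, int] | None = None,
    exclude_years: Iterable[int] = (),
) -> TrendFit:
    """Unweighted OLS of value on calendar year over a year window."""
    s = series.window(window)
    excl = set(exclude_years)
    if excl:
        keep = ~np.isin(s.years, list(excl))
        s = AnnualSeries(s.years[keep], s.values[keep])
    return _ols_trend(s.years, s.values)


def segmented_trend(
    series: AnnualSeries, breakpoint_year: int
) -> tuple[TrendFit | None, TrendFit | None]:
    """Independent trends before (years < breakpoint) and from the
    breakpoint on.  A side with fewer than 3 points is reported as None,
    never fabricated."""
    pre = series.years < breakpoint_year
    out = []
    for mask in (pre, ~pre):
        if mask.sum() >= 3:
            out.append(_ols_trend(series.years[mask], series.values[mask]))
        else:
            out.append(None)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# survival gain rates from life tables
# ---------------------------------------------------------------------------

def survival_change_rate(
    tables: Sequence[LifeTable],
    age: int,
    zero_policy: str = "drop",
    window: tuple[int, int] | None = None,
) -> TrendFit:
    """Annual rate of change of log survival to ``age``.

    OLS of log(lx[age]/radix) on calendar year; zeros in lx are handled
    by the stated policy (see :func:`msalimit.rounding.log_survival`).
    On integer-rounded tables with the ``as_one`` policy this reproduces
    the attenuation artifact: zero-rounded old-age cells enter as fake
    perfect survival and drag the fitted gain rate down.
    """
    ts = sorted(tables, key=lambda t: t.index_year)
    if window is not None:
        ts = [t for t in ts if window[0] <= t.index_year <= window[1]]
    if len(ts) < 3:
        raise InsufficientDataError(f"need >= 3 tables in window, have {len(ts)}")
    years = np.array([t.index_year for t in ts])
    props = np.array([t.lx_at(age) / t.radix for t in ts])
    logs, kept = log_survival(props, zero_policy)
    if kept.size < 3:
        raise InsufficientDataError(
            f"only {kept.size} usable points at age {age} under policy {zero_policy!r}"
        )
    return _ols_trend(years[kept], logs)


def age_of_greatest_gain(
    tables: Sequence[LifeTable],
    ages: Sequence[int],
    zero_policy: str = "drop",
    window: tuple[int, int] | None = None,
) -> int:
    """Candidate age with the largest survival gain rate.

    Candidate ages absent from the tables (e.g. above an age cap) are
    skipped, so on capped tables the result can never exceed the cap —
    the mechanism behind spurious "limits to the age of greatest survival
    gain".  Ties break toward the older age.
    """
    slopes: dict[int, float] = {}
    available = set(tables[0].ages.tolist()) if tables else set()
    for t in tables[1:]:
        available &= set(t.ages.tolist())
    for age in ages:
        if age not in available:
            continue
        slopes[int(age)] = survival_change_rate(tables, int(age), zero_policy, window).slope
    if not slopes:
        raise InsufficientDataError("no candidate age present in all tables")
    best_slope = max(slopes.values())
    # ties toward the older age among those achieving the maximum slope
    best = max(a for a, s in slopes.items() if s == best_slope)
    if np.ptp(list(slopes.values())) < 1e-12:
        warnings.warn("gain rates are flat across candidate ages; argmax is degenerate",
                      stacklevel=2)
    return best


# ---------------------------------------------------------------------------
# record aggregation
# ---------------------------------------------------------------------------

def _ranked_age(records: list[DeathRecord], rank: int) -> float | None:
    if len(records) < rank:
        return None
    # age descending, stable by record id: equal ages occupy consecutive ranks
    ordered = sorted(records, key=lambda r: (-r.age_at_death, r.record_id))
    return ordered[rank - 1].age_at_death


def annual_extreme(
    records: Sequence[DeathRecord], rank: int = 1, by_country: bool = False
) -> AnnualSeries | dict[str, AnnualSeries]:
    """k-th largest reported age at death per death year (k=1 is the MRAD
    series).  Years with fewer than k records are omitted, not padded."""
    if rank < 1:
        raise ParameterError(f"rank must be >= 1, got {rank}")
    if not records:
        raise InsufficientDataError("no records")
    return _aggregate(records, by_country, lambda rs: _ranked_age(rs, rank))


def annual_mean(
    records: Sequence[DeathRecord], by_country: bool = False
) -> AnnualSeries | dict[str, AnnualSeries]:
    """Mean reported age at death (RAD) per death year."""
    if not records:
        raise InsufficientDataError("no records")
    return _aggregate(records, by_country, lambda rs: float(np.mean([r.age_at_death for r in rs])))


def _aggregate(records, by_country, stat):
    def one(group: Sequence[DeathRecord]) -> AnnualSeries:
        byyear: dict[int, list[DeathRecord]] = {}
        for r in group:
            byyear.setdefault(r.death_year, []).append(r)
        years, vals = [], []
        for y in sorted(byyear):
            v = stat(byyear[y])
            if v is not None:
                years.append(y)
                vals.append(v)
        return AnnualSeries(np.array(years, int), np.array(vals, float))

    if not by_country:
        return one(records)
    groups: dict[str, list[DeathRecord]] = {}
    for r in records:
        groups.setdefault(r.country, []).append(r)
    return {c: one(rs) for c, rs in sorted(groups.items())}


def filter_records(
    records: Sequence[DeathRecord],
    countries: Iterable[str] | None = None,
    exclude_months: Iterable[int] = (),
    exclude_ids: Iterable[str] = (),
    window: tuple[int, int] | None = None,
) -> list[DeathRecord]:
    """Drop records failing any predicate; predicates compose in any order."""
    cset = set(countries) if countries is not None else None
    mset, iset = set(exclude_months), set(exclude_ids)
    out = []
    for r in records:
        if cset is not None and r.country not in cset:
            continue
        if r.death_month in mset or r.record_id in iset:
            continue
        if window is not None and not (window[0] <= r.death_year <= window[1]):
            continue
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# LOWESS
# ---------------------------------------------------------------------------

def lowess_smooth(
    series: AnnualSeries, span: float = 0.67, robust_iterations: int = 3
) -> AnnualSeries:
    """Locally weighted regression (degree-1, tricube weights over the
    span-nearest neighbours, bisquare robustness iterations) evaluated at
    the input years."""
    n = len(series)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 points to smooth, have {n}")
    if not 0 < span <= 1:
        raise ParameterError(f"span must be in (0, 1], got {span}")
    if span * n < 2:
        warnings.warn(
            f"span {span} covers fewer than 2 points at n={n}; widening to 2 points",
            stacklevel=2,
        )
        span = 2.0 / n
    smoothed = _sm_lowess(
        series.values,
        series.years.astype(float),
        frac=span,
        it=robust_iterations,
        delta=0.0,
        return_sorted=True,
    )
    return AnnualSeries(series.years.copy(), smoothed[:, 1])


def trend_table(fits: Mapping[str, TrendFit | None]) -> pd.DataFrame:
    """Tidy table of trend fits (group, window, slope, r, p, mse, n)."""
    rows = []
    for name, f in fits.items():
        if f is None:
            rows.append({"group": name, "window_start": None, "window_end": None,
                         "slope": None, "r": None, "p": None, "mse": None, "n": 0})
        else:
            rows.append(
                {
                    "group": name,
                    "window_start": f.window[0],
                    "window_end": f.window[1],
                    "slope": f.slope,
                    "r": f.r,
                    "p": f.p_value,
                    "mse": f.mse,
                    "n": f.n,
                }
            )
    return pd.DataFrame(rows)
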