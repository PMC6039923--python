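"""Synthetic mortality: Gompertz(-Makeham) life tables, supercentenarian
record panels, and the operators that reproduce the data pathologies of
published lifespan-limit analyses (integer rounding, the 110-year age cap,
population pooling with moving coverage windows).

Two q-constructions are provided on purpose.  ``make_loglinear_q_table``
makes ``log(qx)`` *exactly* linear in age, so the maximum-survivable-age
estimator's exactness is provable; ``make_gompertz_lifetable`` integrates
the hazard over each age interval, which is the realistic generator (its
``log(qx)`` is only approximately linear, as in real populations).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .exceptions import ParameterError, ValidationError
from .lifetable import DEFAULT_RADIX, DeathRecord, LifeTable


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz-Makeham hazard h(x) = a*exp(b*x) + c.

    a : baseline hazard per year at age 0 (> 0)
    b : log-hazard slope per year (> 0); human adult mortality roughly
        doubles every ln(2)/b ~ 7-8 years for b ~ 0.09-0.11
    c : Makeham age-independent hazard (>= 0, default 0)
    """

    a: float
    b: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ParameterError(f"a must be > 0, got {self.a}")
        if not self.b > 0:
            raise ParameterError(f"b must be > 0, got {self.b}")
        if self.c < 0:
            raise ParameterError(f"c must be >= 0, got {self.c}")

    def hazard(self, x):
        return self.a * np.exp(self.b * np.asarray(x, float)) + self.c

    def cumulative_hazard(self, x):
        x = np.asarray(x, float)
        return (self.a / self.b) * np.expm1(self.b * x) + self.c * x

    def survival(self, x):
        return np.exp(-self.cumulative_hazard(x))

    @property
    def hazard_unit_age(self) -> float:
        """Age where the Gompertz term a*exp(b*x) crosses 1 (c ignored)."""
        return -math.log(self.a) / self.b


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# life-table constructors
# ---------------------------------------------------------------------------

def make_loglinear_q_table(
    params: GompertzParams,
    max_age: int = 110,
    radix: float = DEFAULT_RADIX,
    population_id: str = "synthetic",
    index_year: int = 0,
) -> LifeTable:
    """Life table whose log(qx) is exactly linear: qx = min(1, a*exp(b*x)).

    q saturates at 1 from age ceil(-ln(a)/b) on, so the cohort is fully
    extinguished inside the table; lx follows the survival recursion.
    Requires c == 0 and a < 1 (otherwise q saturates at age 0).
    """
    if params.c != 0:
        raise ParameterError("make_loglinear_q_table requires a pure Gompertz (c = 0)")
    if params.a >= 1:
        raise ParameterError("a >= 1 saturates q at age 0")
    ages = np.arange(max_age + 1)
    qx = np.minimum(1.0, params.a * np.exp(params.b * ages))
    qx[-1] = 1.0  # terminal open interval closes out the cohort
    lx = radix * np.concatenate([[1.0], np.cumprod(1.0 - qx[:-1])])
    return LifeTable(
        population_id=population_id,
        index_year=index_year,
        table_type="cohort",
        ages=ages,
        qx=qx,
        lx=lx,
        open_interval=True,
        radix=radix,
        precision="exact",
    )


def make_gompertz_lifetable(
    params: GompertzParams,
    max_age: int = 110,
    radix: float = DEFAULT_RADIX,
    population_id: str = "synthetic",
    index_year: int = 0,
    table_type: str = "cohort",
) -> LifeTable:
    """Life table from the integrated Gompertz-Makeham hazard.

    qx = 1 - exp(-H(x)) with H(x) the hazard integrated over [x, x+1);
    lx = radix * S(x) computed directly from the survival function (not by
    chaining 1-qx, which loses all precision once qx rounds to 1.0 in
    float at very old ages).
    """
    ages = np.arange(max_age + 1)
    H = params.cumulative_hazard(ages)
    interval_H = np.diff(params.cumulative_hazard(np.arange(max_age + 2)))
    qx = -np.expm1(-interval_H)
    qx[-1] = 1.0  # terminal open interval
    lx = radix * np.exp(-H)
    return LifeTable(
        population_id=population_id,
        index_year=index_year,
        table_type=table_type,
        ages=ages,
        qx=qx,
        lx=lx,
        open_interval=True,
        radix=radix,
        precision="exact",
    )


def lifetable_from_deaths(
    ages_at_death: np.ndarray,
    max_age: int = 110,
    radix: float = DEFAULT_RADIX,
    population_id: str = "synthetic-empirical",
    index_year: int = 0,
) -> LifeTable:
    """Empirical life table from individual ages at death.

    Deaths are binned to completed years; qx = deaths in [x, x+1) / alive
    at x.  Ages past ``max_age`` fall into the terminal open interval.
    Ages with nobody left alive get qx = NaN (absent, not zero).
    """
    x = np.asarray(ages_at_death, float)
    if np.any(x < 0):
        raise ValidationError("negative age at death")
    n = x.size
    counts = np.bincount(np.minimum(x.astype(int), max_age), minlength=max_age + 1)
    alive = n - np.concatenate([[0], np.cumsum(counts)[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        qx = np.where(alive > 0, counts / alive, np.nan)
    qx[-1] = 1.0
    lx = radix * alive / n
    return LifeTable(
        population_id=population_id,
        index_year=index_year,
        table_type="cohort",
        ages=np.arange(max_age + 1),
        qx=qx,
        lx=lx,
        open_interval=True,
        radix=radix,
        precision="exact",
    )


# ---------------------------------------------------------------------------
# pathology operators
# ---------------------------------------------------------------------------

def apply_integer_rounding(lt: LifeTable, mode: str = "half_away") -> LifeTable:
    """Round lx to the nearest whole survivor, as published tables do.

    ``half_away`` rounds ties away from zero (0.5 -> 1); ``half_even`` is
    banker's rounding.  qx is untouched; the input table is not modified.
    """
    if lt.precision == "integer_rounded":
        warnings.warn("table is already integer-rounded; returning a copy", stacklevel=2)
        return lt.copy()
    if mode == "half_away":
        rounded = np.floor(lt.lx + 0.5)
    elif mode == "half_even":
        rounded = np.round(lt.lx)
    else:
        raise ParameterError(f"unknown rounding mode {mode!r}")
    out = lt.copy()
    out.lx = rounded
    out.precision = "integer_rounded"
    out.validate()
    return out


def apply_age_cap(lt: LifeTable, cap: int = 110) -> LifeTable:
    """Truncate the table at ``cap``, merging older ages into a terminal
    open interval with qx = 1 (the mortality-database convention that
    produces the artificial age ceiling).  lx at the cap is conserved.
    """
    if cap >= lt.max_age:
        warnings.warn(f"cap {cap} >= max age {lt.max_age}; returning a copy", stacklevel=2)
        return lt.copy()
    keep = lt.ages <= cap
    qx = lt.qx[keep].copy()
    qx[-1] = 1.0
    out = lt.copy()
    out.ages = lt.ages[keep].copy()
    out.qx = qx
    out.lx = lt.lx[keep].copy()
    out.open_interval = True
    out.validate()
    return out


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_death_ages(
    params: GompertzParams,
    n: int,
    threshold: float | None = None,
    seed=None,
) -> np.ndarray:
    """i.i.d. ages at death from the (optionally left-truncated) Gompertz
    distribution, by inverse transform on the survival function:

        x = (1/b) * ln(1 - (b/a) * ln U)                    (unconditional)
        x = (1/b) * ln(exp(b*t) - (b/a) * ln U)             (given X > t)

    Requires c == 0 (no closed-form inverse with a Makeham term).
    """
    if params.c != 0:
        raise ParameterError("sample_death_ages requires a pure Gompertz (c = 0)")
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = _as_rng(seed)
    u = rng.random(n)
    ratio = params.b / params.a
    if threshold is None:
        return (1.0 / params.b) * np.log1p(-ratio * np.log(u))
    base = math.exp(params.b * threshold)
    return (1.0 / params.b) * np.log(base - ratio * np.log(u))


def sample_deaths_from_table(lt: LifeTable, n: int, seed=None) -> np.ndarray:
    """Ages at death for ``n`` individuals experiencing the table's qx.

    Integer death ages are drawn multinomially from the table's deaths
    distribution dx / radix; a uniform within-year fraction is added so
    ages are continuous.  Used for finite-cohort parameter-recovery
    studies where the table itself is the ground truth.
    """
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = _as_rng(seed)
    d = lt.dx()
    p = d / d.sum()
    counts = rng.multinomial(n, p)
    ages = np.repeat(lt.ages, counts).astype(float)
    return ages + rng.random(n)


# ---------------------------------------------------------------------------
# record panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountrySpec:
    """One country's contribution to a record panel."""

    country: str
    params: GompertzParams
    coverage: tuple[int, ...]  # calendar years with validation coverage
    annual_count: float  # expected validated deaths above threshold per year

    def __post_init__(self) -> None:
        if self.annual_count < 0:
            raise ParameterError("annual_count must be >= 0")
        object.__setattr__(self, "coverage", tuple(sorted(int(y) for y in self.coverage)))


@dataclass(frozen=True)
class PanelSpec:
    """Specification of a multi-country supercentenarian record panel.

    Per-country coverage windows open and close over calendar time, which
    is exactly the structure that makes naive pooling of the panel produce
    artifactual extreme-age trends.
    """

    countries: tuple[CountrySpec, ...]
    threshold: float = 110.0
    seed: int = 0
    fixed_counts: bool = False  # draw exactly round(annual_count) instead of Poisson

    def __post_init__(self) -> None:
        object.__setattr__(self, "countries", tuple(self.countries))

    # -- YAML round trip --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "seed": self.seed,
            "fixed_counts": self.fixed_counts,
            "countries": [
                {
                    "country": c.country,
                    "a": c.params.a,
                    "b": c.params.b,
                    "c": c.params.c,
                    "coverage": [int(y) for y in c.coverage],
                    "annual_count": c.annual_count,
                }
                for c in self.countries
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PanelSpec":
        return cls(
            countries=tuple(
                CountrySpec(
                    country=c["country"],
                    params=GompertzParams(c["a"], c["b"], c.get("c", 0.0)),
                    coverage=tuple(c["coverage"]),
                    annual_count=c["annual_count"],
                )
                for c in d["countries"]
            ),
            threshold=d.get("threshold", 110.0),
            seed=d.get("seed", 0),
            fixed_counts=d.get("fixed_counts", False),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def simulate_record_panel(spec: PanelSpec, seed=None) -> list[DeathRecord]:
    """Simulate a validated-death record panel.

    For each country and covered year, a Poisson(annual_count) number of
    deaths (or exactly round(annual_count) when ``fixed_counts``) with
    ages drawn from the Gompertz distribution conditional on exceeding the
    threshold, and death months uniform over the year.
    """
    rng = _as_rng(spec.seed if seed is None else seed)
    records: list[DeathRecord] = []
    for country in spec.countries:
        for year in country.coverage:
            if spec.fixed_counts:
                k = int(round(country.annual_count))
            else:
                k = int(rng.poisson(country.annual_count))
            if k == 0:
                continue
            ages = sample_death_ages(country.params, k, threshold=spec.threshold, seed=rng)
            months = rng.integers(1, 13, size=k)
            for i in range(k):
                records.append(
                    DeathRecord(
                        record_id=f"{country.country}-{year}-{i:03d}",
                        age_at_death=float(ages[i]),
                        death_year=int(year),
                        death_month=int(months[i]),
                        country=country.country,
                        validation_status="validated",
                    )
                )
    return records


# ---------------------------------------------------------------------------
# secular improvement
# ---------------------------------------------------------------------------

def make_improving_series(
    params0: GompertzParams,
    annual_decline: float,
    years: Sequence[int],
    max_age: int = 110,
    radix: float = DEFAULT_RADIX,
    population_id: str = "synthetic",
    kind: str = "gompertz",
) -> list[LifeTable]:
    """Period life tables under secular mortality decline.

    The baseline hazard falls multiplicatively, a(y) = a0*(1-annual_decline)
    **(y - y0), with b and c fixed — the simplest mechanism that raises the
    maximum survivable age -ln(a)/b linearly in calendar time.  ``kind``
    selects the q-construction ("gompertz" hazard-integrated, or
    "loglinear").
    """
    if not 0 <= annual_decline < 1:
        raise ParameterError("annual_decline must be in [0, 1)")
    years = list(years)
    if not years:
        return []
    y0 = years[0]
    maker = {"gompertz": make_gompertz_lifetable, "loglinear": make_loglinear_q_table}
    if kind not in maker:
        raise ParameterError(f"unknown kind {kind!r}")
    out = []
    for y in years:
        p = GompertzParams(
            a=params0.a * (1.0 - annual_decline) ** (y - y0), b=params0.b, c=params0.c
        )
        lt = maker[kind](p, max_age=max_age, radix=radix, population_id=population_id, index_year=int(y))
        lt.table_type = "period"
        out.append(lt)
    return out
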