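"""Life-table and death-record containers plus readers/writers for their
standard text dialects.

A :class:`LifeTable` holds one population-year's schedule of age-specific
death probabilities ``qx`` and survivors ``lx`` on a radix (100,000 by
convention).  Tables are either ``exact`` (``lx`` real-valued, consistent
with the survival recursion) or ``integer_rounded`` (``lx`` rounded to the
nearest whole survivor, as mortality databases publish them).  The
distinction is load-bearing: integer rounding is one of the data
pathologies this package diagnoses.

The file dialect is the standard single-age single-year (1x1) life-table
layout: a two-line header, a row of column names
``Year Age mx qx ax lx dx Lx Tx ex``, then whitespace-delimited data rows.
The terminal open age interval is written ``110+`` (or whatever the cap
is); missing cells are ``.`` and are parsed as *absent*, never as zero.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

HMD_COLUMNS = ["Year", "Age", "mx", "qx", "ax", "lx", "dx", "Lx", "Tx", "ex"]
DEFAULT_RADIX = 100_000.0

_SEXES = ("female", "male", "total")
_TABLE_TYPES = ("period", "cohort")
_PRECISIONS = ("exact", "integer_rounded")


@dataclass
class LifeTable:
    """One population-year's age schedule of death probability and survivorship.

    Parameters
    ----------
    population_id : str
        Label for the population (country code, "synthetic", ...).
    index_year : int
        Calendar year for period tables, birth year for cohort tables.
    table_type : {"period", "cohort"}
    ages : ndarray of int
        Ascending completed ages; interval ``[x, x+1)`` is closed-open.
    qx : ndarray of float
        Probability of dying in ``[x, x+1)`` given survival to ``x``; NaN
        marks a missing cell.  The terminal open interval has ``qx == 1``.
    lx : ndarray of float
        Survivors at exact age ``x`` out of ``radix`` births.
    open_interval : bool
        Whether the last age row is an open-ended interval (``"110+"``).
    sex : {"female", "male", "total"}
    radix : float
        Survivors at age 0 (100,000 in the standard databases).
    precision : {"exact", "integer_rounded"}
    """

    population_id: str
    index_year: int
    table_type: str
    ages: np.ndarray
    qx: np.ndarray
    lx: np.ndarray
    open_interval: bool = True
    sex: str = "total"
    radix: float = DEFAULT_RADIX
    precision: str = "exact"

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        self.lx = np.asarray(self.lx, dtype=float)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.table_type not in _TABLE_TYPES:
            raise ValidationError(f"unknown table_type {self.table_type!r}")
        if self.sex not in _SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.precision not in _PRECISIONS:
            raise ValidationError(f"unknown precision {self.precision!r}")
        if not (len(self.ages) == len(self.qx) == len(self.lx)):
            raise ValidationError("ages, qx and lx must have equal length")
        if len(self.ages) == 0:
            raise ValidationError("empty life table")
        if np.any(np.diff(self.ages) <= 0):
            raise ValidationError(
                f"non-monotone ages in {self.population_id} year {self.index_year}"
            )
        finite_q = self.qx[np.isfinite(self.qx)]
        if np.any((finite_q < 0) | (finite_q > 1)):
            raise ValidationError("qx values must lie in [0, 1]")
        if self.open_interval and np.isfinite(self.qx[-1]) and self.qx[-1] != 1.0:
            raise ValidationError("terminal open interval must have qx = 1")
        lx = self.lx[np.isfinite(self.lx)]
        if lx.size and not np.isclose(self.lx[0], self.radix, rtol=0, atol=0.5):
            raise ValidationError(
                f"lx at first age ({self.lx[0]}) does not equal radix ({self.radix})"
            )
        if np.any(np.diff(lx) > 1e-9 * self.radix):
            raise ValidationError("lx must be non-increasing in age")
        if self.precision == "exact":
            self._check_recursion()

    def _check_recursion(self) -> None:
        # lx[x+1] == lx[x] * (1 - qx[x]) to 1e-12 relative (floor at radix eps);
        # only checkable where qx has not saturated to 1.0 in float.
        ok = (
            np.isfinite(self.qx[:-1])
            & np.isfinite(self.lx[:-1])
            & (self.qx[:-1] < 1.0)
            & (np.diff(self.ages) == 1)
        )
        expected = self.lx[:-1][ok] * (1.0 - self.qx[:-1][ok])
        got = self.lx[1:][ok]
        tol = 1e-12 * np.maximum(self.lx[:-1][ok], 1.0) + 1e-12 * self.radix * np.finfo(float).eps
        if np.any(np.abs(got - expected) > tol + 1e-9 * np.abs(expected)):
            raise ValidationError("exact table violates the survival recursion")

    # -- accessors --------------------------------------------------------
    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def _index_of(self, age: int) -> int:
        idx = np.flatnonzero(self.ages == age)
        if idx.size == 0:
            raise KeyError(f"age {age} not present in table {self.population_id}/{self.index_year}")
        return int(idx[0])

    def lx_at(self, age: int) -> float:
        return float(self.lx[self._index_of(age)])

    def qx_at(self, age: int) -> float:
        return float(self.qx[self._index_of(age)])

    def dx(self) -> np.ndarray:
        """Deaths in each age interval; the open interval absorbs all survivors."""
        d = -np.diff(self.lx)
        return np.concatenate([d, [self.lx[-1]]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.index_year,
                "age": self.ages,
                "qx": self.qx,
                "lx": self.lx,
                "open": [False] * (len(self.ages) - 1) + [self.open_interval],
            }
        )

    def copy(self, **changes) -> "LifeTable":
        out = replace(
            self,
            ages=self.ages.copy(),
            qx=self.qx.copy(),
            lx=self.lx.copy(),
        )
        for k, v in changes.items():
            setattr(out, k, v)
        out.validate()
        return out


@dataclass(frozen=True)
class DeathRecord:
    """One validated death: an age at death anchored to a calendar date.

    Only year and month of death are required (the month-of-death record
    filter needs month granularity); the day is optional.
    """

    record_id: str
    age_at_death: float
    death_year: int
    death_month: int
    country: str
    validation_status: str = "validated"
    death_day: int | None = None

    def __post_init__(self) -> None:
        if not self.age_at_death > 0:
            raise ValidationError(f"record {self.record_id}: age_at_death must be > 0")
        if not 1 <= self.death_month <= 12:
            raise ValidationError(f"record {self.record_id}: month {self.death_month} out of range")

    @property
    def death_date(self) -> str:
        if self.death_day is not None:
            return f"{self.death_year:04d}-{self.death_month:02d}-{self.death_day:02d}"
        return f"{self.death_year:04d}-{self.death_month:02d}"


# ---------------------------------------------------------------------------
# life-table text dialect
# ---------------------------------------------------------------------------

_AGE_RE = re.compile(r"^(\d+)(\+?)$")


def _parse_header(lines: Sequence[str]) -> tuple[str, str]:
    """Population id and sex from the first header line (best effort)."""
    parts = [p.strip() for p in lines[0].split(",")]
    population_id = parts[0] if parts and parts[0] else "unknown"
    sex = "total"
    for p in parts[1:]:
        low = p.lower().rstrip("s")
        if low in ("female", "male", "total"):
            sex = low
    return population_id, sex


def read_hmd_lifetable(path: str | Path, table_type: str = "period") -> list[LifeTable]:
    """Read a 1x1 life-table file into one :class:`LifeTable` per year.

    ``lx`` is stored as published — integers — so the returned tables have
    ``precision="integer_rounded"``.  Missing cells (``.``) become NaN;
    they are never coerced to zero.
    """
    if table_type not in _TABLE_TYPES:
        raise ValidationError(f"unknown table_type {table_type!r}")
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: expected a 2-line header plus a column row")
    population_id, sex = _parse_header(lines)
    cols = lines[2].split()
    if cols != HMD_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {' '.join(HMD_COLUMNS)}, found {' '.join(cols)}"
        )

    rows = []
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != len(HMD_COLUMNS):
            raise FormatError(f"{path}:{lineno}: expected {len(HMD_COLUMNS)} fields")
        rows.append(fields)

    tables: list[LifeTable] = []
    if not rows:
        return tables
    frame = pd.DataFrame(rows, columns=HMD_COLUMNS)
    for year, grp in frame.groupby("Year", sort=True):
        ages, open_flags = [], []
        for token in grp["Age"]:
            m = _AGE_RE.match(token)
            if m is None:
                raise FormatError(f"{path}: unparseable age {token!r} in year {year}")
            ages.append(int(m.group(1)))
            open_flags.append(m.group(2) == "+")
        ages_arr = np.array(ages)
        if np.any(np.diff(ages_arr) <= 0):
            raise ValidationError(f"{path}: non-monotone ages in year {year}")
        if any(open_flags[:-1]):
            raise ValidationError(f"{path}: open interval before the last age in year {year}")

        def col(name: str) -> np.ndarray:
            # python float() is correctly rounded; pandas' parser can be 1 ulp off
            return np.array([np.nan if s == "." else float(s) for s in grp[name]])

        qx, lx = col("qx"), col("lx")
        # files with fractional lx are exact-precision synthetic tables;
        # published tables carry whole survivors only
        finite_lx = lx[np.isfinite(lx)]
        precision = "integer_rounded" if np.all(finite_lx == np.round(finite_lx)) else "exact"
        tables.append(
            LifeTable(
                population_id=population_id,
                index_year=int(year),
                table_type=table_type,
                sex=sex,
                ages=ages_arr,
                qx=qx,
                lx=lx,
                open_interval=bool(open_flags[-1]),
                radix=float(lx[0]) if np.isfinite(lx[0]) else DEFAULT_RADIX,
                precision=precision,
            )
        )
    return tables


def _fmt(value: float, *, integer: bool = False) -> str:
    if not np.isfinite(value):
        return "."
    if integer:
        return str(int(round(value)))
    return format(float(value), ".17g")


def write_lifetable(tables: Iterable[LifeTable], path: str | Path) -> None:
    """Write tables in the dialect :func:`read_hmd_lifetable` accepts.

    Integer-rounded ``lx`` is written without a decimal point; exact ``lx``
    keeps full float precision so a write/read round trip is the identity.
    Columns the container does not carry (mx, ax, Lx, Tx, ex) are written
    as missing (``.``); dx is derived from lx.
    """
    tables = list(tables)
    path = Path(path)
    if tables:
        pop_ids = {t.population_id for t in tables}
        types = {t.table_type for t in tables}
        if len(types) > 1:
            raise ValidationError(f"cannot mix table types in one file: {sorted(types)}")
        if len(pop_ids) > 1:
            raise ValidationError(f"cannot mix populations in one file: {sorted(pop_ids)}")
        population_id, table_type, sex = tables[0].population_id, tables[0].table_type, tables[0].sex
    else:
        population_id, table_type, sex = "empty", "period", "total"

    out = [f"{population_id}, {sex}, Life tables ({table_type} 1x1)", ""]
    out.append("  ".join(HMD_COLUMNS))
    for t in tables:
        integer = t.precision == "integer_rounded"
        d = t.dx()
        for i, age in enumerate(t.ages):
            age_tok = f"{age}+" if (i == len(t.ages) - 1 and t.open_interval) else str(age)
            out.append(
                "  ".join(
                    [
                        str(t.index_year),
                        age_tok,
                        ".",  # mx
                        _fmt(t.qx[i]),
                        ".",  # ax
                        _fmt(t.lx[i], integer=integer),
                        _fmt(d[i], integer=integer),
                        ".",  # Lx
                        ".",  # Tx
                        ".",  # ex
                    ]
                )
            )
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# death-record CSV
# ---------------------------------------------------------------------------

RECORD_COLUMNS = ["id", "age_years", "death_date", "country", "status"]
_DATE_RE = re.compile(r"^(\d{4})-(\d{2})(?:-(\d{2}))?$")


def read_death_records(path: str | Path) -> list[DeathRecord]:
    """Read a validated-death record table (CSV with headers
    ``id, age_years, death_date, country, status``).

    Dates must be ISO (``YYYY-MM`` or ``YYYY-MM-DD``).  Any unparseable row
    is reported with its row index and the whole file is rejected — a
    silently dropped or zeroed record would bias every downstream extreme-
    value series.
    """
    path = Path(path)
    records: list[DeathRecord] = []
    errors: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != RECORD_COLUMNS:
            raise FormatError(
                f"{path}: expected header {','.join(RECORD_COLUMNS)}, found {reader.fieldnames}"
            )
        for idx, row in enumerate(reader, start=1):
            try:
                age = float(row["age_years"])
                m = _DATE_RE.match(row["death_date"].strip())
                if m is None:
                    raise ValueError(f"bad date {row['death_date']!r}")
                records.append(
                    DeathRecord(
                        record_id=row["id"].strip(),
                        age_at_death=age,
                        death_year=int(m.group(1)),
                        death_month=int(m.group(2)),
                        death_day=int(m.group(3)) if m.group(3) else None,
                        country=row["country"].strip(),
                        validation_status=row["status"].strip(),
                    )
                )
            except (ValueError, ValidationError) as exc:
                errors.append(f"row {idx}: {exc}")
    if errors:
        raise FormatError(f"{path}: " + "; ".join(errors))
    return records


def write_death_records(records: Iterable[DeathRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for r in records:
            writer.writerow(
                [r.record_id, format(r.age_at_death, ".10g"), r.death_date, r.country, r.validation_status]
            )
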