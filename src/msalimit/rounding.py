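"""Diagnostics for integer-rounding error in published survivorship and
the log-transform policies whose confusion manufactures spurious survival
plateaus.

Published life tables report lx as whole survivors out of 100,000, so at
ages where survival approaches 1 in 100,000 the relative rounding error
explodes and many cells round to exactly zero.  What a regression then
does with log(0) decides the result: dropping the zeros is defensible;
silently mapping log(0) to log(1) = 0 injects fake perfect survival into
the oldest ages.  Both policies are implemented so the artifact can be
reproduced and measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError, ZeroLogError
from .lifetable import LifeTable

ZERO_POLICIES = ("drop", "as_one", "fail")


@dataclass
class RoundingReport:
    """Age-wise summary of (rounded lx - exact lx) across a table collection."""

    ages: np.ndarray
    q025: np.ndarray
    median: np.ndarray
    q975: np.ndarray
    zero_fraction: np.ndarray  # share of tables with rounded lx == 0 at each age
    n_tables: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.ages,
                "q2.5": self.q025,
                "median": self.median,
                "q97.5": self.q975,
                "zero_fraction": self.zero_fraction,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _table_key(t: LifeTable) -> tuple[str, int]:
    return (t.population_id, t.index_year)


def compute_rounding_errors(
    exact: Sequence[LifeTable], rounded: Sequence[LifeTable]
) -> RoundingReport:
    """Quantify rounding error age-wise over matched table collections.

    Collections are aligned by (population_id, index_year); the error at
    each age is rounded lx - exact lx on the survivor-count scale (never
    the log scale, which is undefined at zero).  The report carries the
    2.5/50/97.5 percent quantiles and the share of tables whose rounded
    lx is exactly zero, per age.
    """
    ex = {_table_key(t): t for t in exact}
    ro = {_table_key(t): t for t in rounded}
    if set(ex) != set(ro):
        missing = set(ex) ^ set(ro)
        raise ValidationError(f"collections are misaligned; unmatched keys: {sorted(missing)}")
    if not ex:
        raise ValidationError("empty collections")
    keys = sorted(ex)
    ages = ex[keys[0]].ages
    for k in keys:
        if not np.array_equal(ex[k].ages, ages) or not np.array_equal(ro[k].ages, ages):
            raise ValidationError(f"age grids differ for {k}")
    errors = np.vstack([ro[k].lx - ex[k].lx for k in keys])
    zeros = np.vstack([ro[k].lx == 0 for k in keys])
    q = np.nanpercentile(errors, [2.5, 50.0, 97.5], axis=0)
    return RoundingReport(
        ages=ages.copy(),
        q025=q[0],
        median=q[1],
        q975=q[2],
        zero_fraction=zeros.mean(axis=0),
        n_tables=len(keys),
    )


def zero_rounded_fraction(tables: Iterable[LifeTable], age_min: float = 90) -> float:
    """Fraction of (table, age) cells above ``age_min`` with lx rounded to 0."""
    total = zeros = 0
    for t in tables:
        if t.precision != "integer_rounded":
            raise ValidationError(
                f"zero_rounded_fraction requires integer-rounded tables, got {t.precision!r}"
            )
        mask = (t.ages > age_min) & np.isfinite(t.lx)
        total += int(mask.sum())
        zeros += int(np.sum(t.lx[mask] == 0))
    if total == 0:
        raise ValidationError(f"no cells above age {age_min}")
    return zeros / total


def log_survival(
    values: Sequence[float], zero_policy: str = "drop"
) -> tuple[np.ndarray, np.ndarray]:
    """Log-transform survivor proportions under an explicit zero policy.

    Returns ``(logged, kept_index)`` where ``kept_index`` maps each output
    back to its input position — mandatory so downstream regressions can
    report how many points a policy discarded.

    Policies:
      drop   — zeros removed (the defensible choice);
      as_one — log(0) replaced by 0, i.e. treated as log(1): retained only
               to reproduce the artifact it creates;
      fail   — any zero raises :class:`ZeroLogError`.
    """
    v = np.asarray(values, float)
    if np.any(v < 0) or np.any(v > 1):
        raise ValidationError("survivor proportions must lie in [0, 1]")
    if zero_policy not in ZERO_POLICIES:
        raise ValidationError(f"unknown zero_policy {zero_policy!r}")
    zero = v == 0
    if zero_policy == "fail":
        if zero.any():
            raise ZeroLogError(f"zero survival at positions {np.flatnonzero(zero).tolist()}")
        return np.log(v), np.arange(v.size)
    if zero_policy == "drop":
        kept = np.flatnonzero(~zero)
        return np.log(v[kept]), kept
    # as_one
    out = np.where(zero, 0.0, np.log(np.where(zero, 1.0, v)))
    return out, np.arange(v.size)
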