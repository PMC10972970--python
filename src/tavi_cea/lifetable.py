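"""Synthetic sex-specific lifetables for long-term survival extrapolation.

Beyond the two-year trial window the model continues cohort mortality from
general-population lifetables.  The published French (INSEE) tables are not
redistributed here; instead a Gompertz hazard — the standard description of
adult mortality at ages 70+ — is calibrated per sex so that the remaining
life expectancy at age 74 matches the published summaries (13.0 years for
males, 15.8 for females).  A user-supplied lifetable file (columns
``sex,age,q_annual``) overrides the synthetic one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

AGE_MIN = 60
AGE_CAP = 110   # q(AGE_CAP) is forced to 1


@dataclass(frozen=True)
class GompertzParams:
    """Gompertz hazard ``h(a) = level * exp(shape * (a - reference_age))``."""

    level: float          # baseline annual hazard at the reference age
    shape: float          # exponential age slope, per year
    reference_age: float = 74.0

    def validate(self) -> None:
        if self.level <= 0 or self.shape <= 0:
            raise ValueError(
                f"Gompertz level and shape must be > 0, got "
                f"level={self.level}, shape={self.shape}"
            )


@dataclass
class Lifetable:
    """Annual death probabilities ``q_annual`` for integer ages 60..110."""

    sex: str
    ages: np.ndarray
    q_annual: np.ndarray

    def validate(self) -> None:
        if np.any(self.q_annual < 0) or np.any(self.q_annual > 1):
            raise ValueError(f"lifetable[{self.sex}]: q_annual outside [0, 1]")
        if self.q_annual[-1] != 1.0:
            raise ValueError(f"lifetable[{self.sex}]: q_annual at age cap must be 1")
        if np.any(np.diff(self.q_annual) < 0):
            raise ValueError(f"lifetable[{self.sex}]: q_annual must be non-decreasing")

    def q_at(self, age) -> np.ndarray | float:
        """Annual death probability at (possibly fractional) age.

        Linear interpolation between integer ages; ages at or beyond the cap
        return 1 (certain death within the year).
        """
        age = np.asarray(age, dtype=float)
        q = np.interp(age, self.ages, self.q_annual, left=self.q_annual[0], right=1.0)
        q = np.where(age >= AGE_CAP, 1.0, q)
        return float(q) if q.ndim == 0 else q


def make_gompertz_lifetable(params: GompertzParams, sex: str) -> Lifetable:
    """Build a lifetable from a Gompertz hazard: ``q(a) = 1 - exp(-h(a))``."""
    params.validate()
    ages = np.arange(AGE_MIN, AGE_CAP + 1)
    hazard = params.level * np.exp(params.shape * (ages - params.reference_age))
    q = 1.0 - np.exp(-hazard)   # increasing in age by construction
    q[-1] = 1.0                 # cap rule: certain death in the final year
    table = Lifetable(sex=sex, ages=ages.astype(float), q_annual=q)
    table.validate()
    return table


def life_expectancy(table: Lifetable, age: int = 74, convention: str = "complete") -> float:
    """Remaining life expectancy at an integer age from the annual table.

    ``curtate`` sums the survival probabilities to each later birthday
    (whole years lived); ``complete`` adds the conventional half year for the
    part-year lived in the year of death, matching how published lifetable
    summaries report life expectancy and how the monthly cohort model
    accrues survival time.
    """
    if convention not in ("complete", "curtate"):
        raise ValueError(f"unknown life-expectancy convention {convention!r}")
    idx = np.searchsorted(table.ages, age)
    if idx >= len(table.ages) or table.ages[idx] != age:
        raise ValueError(f"age {age} outside lifetable range")
    survival = np.cumprod(1.0 - table.q_annual[idx:])
    le = float(np.sum(survival))
    if convention == "complete":
        le += 0.5
    return le


def calibrate_to_life_expectancy(
    target_le: float,
    shape: float = 0.10,
    sex: str = "unspecified",
    reference_age: float = 74.0,
    convention: str = "complete",
    tol: float = 1e-4,
) -> GompertzParams:
    """Find the Gompertz level whose lifetable hits a life-expectancy target.

    Root-finds on log(level) so that the remaining life expectancy at age 74
    equals ``target_le`` to within ±0.01 years (the root tolerance is far
    tighter).  Raises if the target is not bracketed for the given shape.
    """
    def le_of(log_level: float) -> float:
        params = GompertzParams(level=float(np.exp(log_level)), shape=shape,
                                reference_age=reference_age)
        return life_expectancy(make_gompertz_lifetable(params, sex),
                               age=int(reference_age), convention=convention)

    lo, hi = np.log(1e-8), np.log(50.0)
    f_lo, f_hi = le_of(lo) - target_le, le_of(hi) - target_le
    if f_lo * f_hi > 0:
        raise ValueError(
            f"life-expectancy target {target_le} y not bracketed for shape "
            f"{shape} (achievable range ~[{le_of(hi):.2f}, {le_of(lo):.2f}] y "
            f"under the {convention} convention); try a different shape"
        )
    root = brentq(lambda x: le_of(x) - target_le, lo, hi, xtol=tol)
    return GompertzParams(level=float(np.exp(root)), shape=shape,
                          reference_age=reference_age)


def annual_to_monthly(q_annual):
    """Constant-hazard conversion of an annual to a monthly death probability."""
    q = np.asarray(q_annual, dtype=float)
    out = 1.0 - (1.0 - np.minimum(q, 1.0)) ** (1.0 / 12.0)
    return float(out) if out.ndim == 0 else out


def cohort_monthly_mortality(age, pct_female: float, rr: float,
                             table_male: Lifetable, table_female: Lifetable):
    """Monthly death probability for a fixed male/female mix at a given age.

    ``q_mix = min(1, rr * (mix * q_f + (1 - mix) * q_m))`` converted to a
    monthly probability.  This mixes the sexes' hazards at fixed weights; the
    cohort engine instead tracks the sexes as separate sub-cohorts, which
    lets the surviving mix drift female-ward with age — this function is the
    per-sex building block and the fixed-mix approximation used in checks.
    """
    if not 0.0 <= pct_female <= 1.0:
        raise ValueError(f"pct_female must be in [0, 1], got {pct_female}")
    if rr < 0:
        raise ValueError(f"rr must be >= 0, got {rr}")
    q_mix = rr * (pct_female * np.asarray(table_female.q_at(age))
                  + (1.0 - pct_female) * np.asarray(table_male.q_at(age)))
    return annual_to_monthly(np.minimum(q_mix, 1.0))


def build_lifetables(shape: float, le_target_male: float, le_target_female: float,
                     convention: str = "complete") -> dict[str, Lifetable]:
    """Calibrated male/female lifetable pair for the model configuration."""
    key = (round(shape, 12), round(le_target_male, 6), round(le_target_female, 6), convention)
    if key not in _TABLE_CACHE:
        _TABLE_CACHE[key] = {
            "male": make_gompertz_lifetable(
                calibrate_to_life_expectancy(le_target_male, shape=shape, sex="male",
                                             convention=convention), "male"),
            "female": make_gompertz_lifetable(
                calibrate_to_life_expectancy(le_target_female, shape=shape, sex="female",
                                             convention=convention), "female"),
        }
    return _TABLE_CACHE[key]


_TABLE_CACHE: dict = {}


def load_lifetable_file(path: str | Path) -> dict[str, Lifetable]:
    """Read a user lifetable override: delimited text, columns sex,age,q_annual."""
    df = pd.read_csv(path)
    expected = {"sex", "age", "q_annual"}
    if not expected.issubset(df.columns):
        raise ValueError(f"lifetable file must have columns {sorted(expected)}")
    tables = {}
    for sex, grp in df.groupby("sex"):
        grp = grp.sort_values("age")
        table = Lifetable(sex=str(sex), ages=grp["age"].to_numpy(dtype=float),
                          q_annual=grp["q_annual"].to_numpy(dtype=float))
        table.validate()
        tables[str(sex)] = table
    for sex in ("male", "female"):
        if sex not in tables:
            raise ValueError(f"lifetable file missing rows for sex={sex!r}")
    return tables


def write_lifetable_file(tables: dict[str, Lifetable], path: str | Path) -> None:
    rows = [
        {"sex": t.sex, "age": int(a), "q_annual": float(q)}
        for t in tables.values()
        for a, q in zip(t.ages, t.q_annual)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
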