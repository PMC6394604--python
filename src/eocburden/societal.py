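"""Direct non-healthcare costs (formal and informal care) and indirect costs
(productivity losses) by the human-capital method.

Formal care (public 1.5 h/day, private 8 h/day) is attached to the last 48
days of life; informal care (10.3 h/day for 93.4% of patients) accrues by
default over post-progression occupancy and is valued by the proxy-good
method at the professional caregiver wage.  Indirect costs cover the initial
temporary leave of stable patients (30% lose 60 days, 70% lose 70), sick
leave from progression until death or retirement (booked as permanent once it
exceeds one year), and foregone gross wages of deaths before retirement age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import CohortTrace
from .parameters import (DomainError, EconomicSettings, ModelParameters,
                         ParameterError)

DAYS_PER_YEAR = 365.25


@dataclass
class CareAssumptions:
    """Formal/informal care coverage, daily hours and the caregiver wage."""

    pct_private: float = 0.174
    pct_public: float = 0.095
    pct_informal: float = 0.934
    hours_public: float = 1.5      # per day
    hours_private: float = 8.0
    hours_informal: float = 10.3
    wage_per_hour: float = 13.56   # proxy-good valuation, euros/hour
    formal_care_days: float = 48.0

    def validate(self) -> None:
        for name in ("pct_private", "pct_public", "pct_informal"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"care.{name} not in [0, 1]")
        for name in ("hours_public", "hours_private", "hours_informal",
                     "wage_per_hour", "formal_care_days"):
            if getattr(self, name) < 0:
                raise ParameterError(f"care.{name} must be >= 0")


@dataclass
class LeavePolicy:
    """Initial temporary-leave split for stable patients."""

    short_fraction: float = 0.30
    short_days: float = 60.0
    long_days: float = 70.0

    @property
    def expected_days(self) -> float:
        return (self.short_fraction * self.short_days
                + (1.0 - self.short_fraction) * self.long_days)


class LabourSchedule:
    """Age-specific female employment rates and gross annual wages.

    Lookup floors the age and clamps to the tabulated range; employment is
    zero from the retirement age onwards by construction of the generator.
    """

    def __init__(self, ages, employment_rate, annual_wage):
        self.ages = np.asarray(list(ages), dtype=int)
        self.employment_rate = np.asarray(list(employment_rate), dtype=float)
        self.annual_wage = np.asarray(list(annual_wage), dtype=float)
        if np.any(np.diff(self.ages) != 1):
            raise ParameterError("labour: ages must be contiguous")
        if np.any((self.employment_rate < 0) | (self.employment_rate > 1)):
            raise ParameterError("labour: employment_rate not in [0, 1]")
        if np.any(self.annual_wage < 0):
            raise ParameterError("labour: wages must be >= 0")

    def _idx(self, age: float) -> int:
        return int(np.clip(math.floor(age) - self.ages[0], 0,
                           self.ages.size - 1))

    def employment(self, age: float) -> float:
        return float(self.employment_rate[self._idx(age)])

    def wage(self, age: float) -> float:
        return float(self.annual_wage[self._idx(age)])

    def to_records(self) -> list:
        return self.to_frame().to_dict(orient="records")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages,
                             "employment_rate": self.employment_rate,
                             "annual_wage": self.annual_wage})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_records(cls, records) -> "LabourSchedule":
        df = pd.DataFrame(records)
        return cls(df["age"], df["employment_rate"], df["annual_wage"])

    @classmethod
    def from_csv(cls, path) -> "LabourSchedule":
        df = pd.read_csv(path, comment="#")
        return cls(df["age"], df["employment_rate"], df["annual_wage"])


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _discount(elapsed: float, econ: EconomicSettings) -> float:
    return (1.0 + econ.discount_rate_annual) ** (-elapsed)


def _growth(elapsed: float, econ: EconomicSettings) -> float:
    return (1.0 + econ.productivity_growth) ** elapsed


def _entry_offset(trace: CohortTrace, econ: EconomicSettings) -> float:
    return float(trace.entry_year - econ.first_year)


# ---------------------------------------------------------------------------
# direct non-healthcare costs
# ---------------------------------------------------------------------------

@dataclass
class FormalCareCost:
    public: float
    private: float

    @property
    def total(self) -> float:
        return self.public + self.private


def formal_care_cost_per_death(care: CareAssumptions) -> FormalCareCost:
    """Expected formal-care cost per dying patient over the last 48 days."""
    care.validate()
    base = care.formal_care_days * care.wage_per_hour
    return FormalCareCost(
        public=care.pct_public * care.hours_public * base,
        private=care.pct_private * care.hours_private * base)


def informal_care_cost(trace: CohortTrace, care: CareAssumptions,
                       econ: EconomicSettings,
                       window: str = "post_progression",
                       by_year: bool = False):
    """Discounted informal-care cost of one cohort.

    The accrual window is configurable: ``post_progression`` (default) values
    caregiver hours over post-progression occupancy, ``last_48_days`` attaches
    a 48-day block to each death, and ``whole_disease`` uses all alive
    occupancy.  Returns the cohort total, or per-calendar-year amounts if
    *by_year*.
    """
    care.validate()
    t = econ.cycle_years
    offset = _entry_offset(trace, econ)
    per_day = care.pct_informal * care.hours_informal * care.wage_per_hour
    n = trace.frac_stable.size
    amounts = np.zeros(n)

    if window == "post_progression":
        occ = trace.frac_postprog
        for c in range(n - 1):
            amounts[c] = (occ[c] * per_day * econ.cycle_days
                          * _discount(offset + c * t, econ))
    elif window == "whole_disease":
        occ = trace.alive()
        for c in range(n - 1):
            amounts[c] = (occ[c] * per_day * econ.cycle_days
                          * _discount(offset + c * t, econ))
    elif window == "last_48_days":
        for c in range(1, n):
            amounts[c] = (trace.new_deaths[c] * per_day * 48.0
                          * _discount(offset + c * t, econ))
    else:
        raise ParameterError(f"unknown informal-care window {window!r}")

    amounts *= trace.size
    if by_year:
        return _bucket_by_year(amounts, trace, econ)
    return float(amounts.sum())


# ---------------------------------------------------------------------------
# indirect costs (human-capital method)
# ---------------------------------------------------------------------------

def temporary_leave_cost(trace: CohortTrace, schedule: LabourSchedule,
                         econ: EconomicSettings,
                         policy: LeavePolicy | None = None) -> float:
    """Initial temporary-leave loss, once per diagnosed working-age patient.

    Expected lost days are the leave-policy mean (67 under defaults), valued
    at the employment rate and daily gross wage at the age of diagnosis, with
    productivity growth and discounting at the entry time.  Zero for cohorts
    diagnosed at or above the retirement age.
    """
    policy = policy or LeavePolicy()
    age = float(trace.attained_age[0])
    if age >= econ.retirement_age:
        return 0.0
    offset = _entry_offset(trace, econ)
    daily = schedule.wage(age) / DAYS_PER_YEAR
    loss = (trace.size * schedule.employment(age) * policy.expected_days
            * daily * _growth(offset, econ) * _discount(offset, econ))
    return float(loss)


def permanent_and_progression_leave_cost(trace: CohortTrace,
                                         schedule: LabourSchedule,
                                         econ: EconomicSettings,
                                         by_year: bool = False):
    """Sick-leave losses from progression until death or retirement.

    Each progression sub-cohort (progressed at cycle *c0* before retirement
    age) accrues lost wages while its members survive post-progression and
    remain under the retirement age.  Person-time within one year of
    progression books to the temporary-disability row; beyond one year to
    permanent disability.  Returns ``(permanent, progression_temporary)``
    totals, or per-year arrays when *by_year*.
    """
    t = econ.cycle_years
    offset = _entry_offset(trace, econ)
    ages = trace.attained_age
    n = ages.size
    ret = econ.retirement_age
    perm = np.zeros(n)
    temp = np.zeros(n)

    for c0 in range(1, n):
        n_prog = trace.new_progressions[c0]
        age0 = ages[c0]
        if n_prog <= 0 or age0 >= ret:
            continue
        emp = schedule.employment(age0)
        if emp <= 0:
            continue
        surv = trace.postprogression_survival(c0)
        daily = schedule.wage(age0) / DAYS_PER_YEAR
        for k in range(surv.size - 1):
            c = c0 + k
            if c >= n - 1:
                break
            age_c = ages[c]
            if age_c >= ret:
                break
            # fraction of this cycle spent under the retirement age
            frac = min(1.0, (ret - age_c) / t)
            elapsed = offset + c * t
            amount = (n_prog * surv[k] * emp * daily * econ.cycle_days * frac
                      * _growth(elapsed, econ) * _discount(elapsed, econ))
            if (k + 1) * t <= 1.0:
                temp[c] += amount
            else:
                perm[c] += amount

    perm *= trace.size
    temp *= trace.size
    if by_year:
        return (_bucket_by_year(perm, trace, econ),
                _bucket_by_year(temp, trace, econ))
    return float(perm.sum()), float(temp.sum())


def premature_mortality_cost(trace: CohortTrace, schedule: LabourSchedule,
                             econ: EconomicSettings,
                             discounted: bool = True,
                             by_year: bool = False):
    """Foregone gross wages of deaths occurring before the retirement age.

    For a death at attained age ``a < retirement_age`` the loss sums
    ``employment(age) x wage(age)`` over the years from *a* to retirement,
    with annual productivity growth, discounted to the model start (the
    discount can be switched off).
    """
    t = econ.cycle_years
    offset = _entry_offset(trace, econ)
    ages = trace.attained_age
    n = ages.size
    ret = econ.retirement_age
    amounts = np.zeros(n)

    for c in range(1, n):
        deaths = trace.new_deaths[c]
        a = ages[c]
        if deaths <= 0 or a >= ret:
            continue
        elapsed0 = offset + c * t
        loss = 0.0
        k = 0
        pos = a
        while pos < ret:
            seg = min(1.0, ret - pos)
            factor = _growth(elapsed0 + k, econ)
            if discounted:
                factor *= _discount(elapsed0 + k, econ)
            loss += (seg * schedule.employment(pos) * schedule.wage(pos)
                     * factor)
            pos += seg
            k += 1
        amounts[c] = deaths * loss

    amounts *= trace.size
    if by_year:
        return _bucket_by_year(amounts, trace, econ)
    return float(amounts.sum())


# ---------------------------------------------------------------------------
# calendar bucketing
# ---------------------------------------------------------------------------

def _bucket_by_year(amounts: np.ndarray, trace: CohortTrace,
                    econ: EconomicSettings) -> pd.Series:
    """Sum per-cycle amounts into calendar-year reporting buckets."""
    cpy = econ.cycles_per_year
    cycles = np.arange(amounts.size)
    year_idx = np.minimum(cycles // cpy,
                          econ.last_year - trace.entry_year)
    years = trace.entry_year + year_idx
    return pd.Series(amounts).groupby(years).sum()
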