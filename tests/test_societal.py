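"""Care costs and human-capital productivity losses."""

import math

import numpy as np
import pytest

import eocburden as eb
from eocburden import societal as sc
from eocburden.markov import CohortTrace

T_CYCLE = 21 / 365.25


def make_trace(age_dx, occ_pp_cycles=0, death_cycle=None, n=54,
               entry_year=2017):
    """Hand-built trace: optional post-progression block and one death."""
    s = np.ones(n + 1)
    p = np.zeros(n + 1)
    d = np.zeros(n + 1)
    new_prog = np.zeros(n + 1)
    new_dead = np.zeros(n + 1)
    if occ_pp_cycles:
        s[1:] = 0.0
        p[1:1 + occ_pp_cycles] = 1.0
        new_prog[1] = 1.0
        if 1 + occ_pp_cycles <= n:
            d[1 + occ_pp_cycles:] = 1.0
            new_dead[1 + occ_pp_cycles] = 1.0
            p[1 + occ_pp_cycles:] = 0.0
    elif death_cycle is not None:
        s[death_cycle:] = 0.0
        d[death_cycle:] = 1.0
        new_dead[death_cycle] = 1.0
    prps = np.zeros(n)
    if occ_pp_cycles:
        prps[1:occ_pp_cycles] = 1.0
    return CohortTrace(
        stage_label="I", entry_year=entry_year, size=1.0,
        attained_age=age_dx + T_CYCLE * np.arange(n + 1),
        frac_stable=s, frac_postprog=p, frac_dead=d,
        new_progressions=new_prog, new_deaths=new_dead, prps=prps)


@pytest.fixture()
def zero_discount_econ():
    econ = eb.EconomicSettings()
    econ.discount_rate_annual = 0.0
    econ.productivity_growth = 0.0
    return econ


@pytest.fixture()
def flat_labour():
    """Full employment at a flat wage of 365.25 euros/year (1/day)."""
    ages = range(16, 101)
    return sc.LabourSchedule(ages, [1.0 if a < 65 else 0.0 for a in ages],
                             [365.25] * len(range(16, 101)))


class TestFormalCare:
    def test_zero_wage(self):
        care = sc.CareAssumptions(wage_per_hour=0.0)
        assert sc.formal_care_cost_per_death(care).total == 0.0

    def test_default_components(self):
        fc = sc.formal_care_cost_per_death(sc.CareAssumptions())
        assert fc.private == pytest.approx(0.174 * 8 * 13.56 * 48)
        assert fc.public == pytest.approx(0.095 * 1.5 * 13.56 * 48)
        assert fc.private == pytest.approx(906.02496, rel=1e-12)
        assert fc.public == pytest.approx(92.7504, rel=1e-12)


class TestInformalCare:
    def test_no_progression_no_cost_under_default_window(self,
                                                         zero_discount_econ):
        tr = make_trace(60.0)  # stays stable throughout
        assert sc.informal_care_cost(tr, sc.CareAssumptions(),
                                     zero_discount_econ) == 0.0

    def test_hand_value_for_210_postprogression_days(self,
                                                     zero_discount_econ):
        tr = make_trace(60.0, occ_pp_cycles=10)  # 10 cycles = 210 days
        got = sc.informal_care_cost(tr, sc.CareAssumptions(),
                                    zero_discount_econ)
        assert got == pytest.approx(0.934 * 10.3 * 13.56 * 210, rel=1e-12)

    def test_linear_in_hours(self, zero_discount_econ):
        tr = make_trace(60.0, occ_pp_cycles=10)
        base = sc.informal_care_cost(tr, sc.CareAssumptions(),
                                     zero_discount_econ)
        doubled = sc.informal_care_cost(
            tr, sc.CareAssumptions(hours_informal=2 * 10.3),
            zero_discount_econ)
        assert doubled == pytest.approx(2 * base)

    def test_last_48_days_window_attaches_to_deaths(self, zero_discount_econ):
        tr = make_trace(60.0, occ_pp_cycles=10)
        got = sc.informal_care_cost(tr, sc.CareAssumptions(),
                                    zero_discount_econ, window="last_48_days")
        assert got == pytest.approx(0.934 * 10.3 * 13.56 * 48, rel=1e-12)


class TestTemporaryLeave:
    def test_zero_for_retired_cohort(self, flat_labour, zero_discount_econ):
        tr = make_trace(68.1)
        assert sc.temporary_leave_cost(tr, flat_labour,
                                       zero_discount_econ) == 0.0

    def test_zero_when_nobody_works(self, zero_discount_econ):
        ages = range(16, 101)
        idle = sc.LabourSchedule(ages, [0.0] * 85, [20000.0] * 85)
        tr = make_trace(50.0)
        assert sc.temporary_leave_cost(tr, idle, zero_discount_econ) == 0.0

    def test_expected_days_are_67_at_unit_daily_wage(self, flat_labour,
                                                     zero_discount_econ):
        tr = make_trace(50.0)
        got = sc.temporary_leave_cost(tr, flat_labour, zero_discount_econ)
        assert got == pytest.approx(0.3 * 60 + 0.7 * 70, rel=1e-12)


class TestProgressionLeave:
    def test_zero_when_retirement_below_all_ages(self, flat_labour,
                                                 zero_discount_econ):
        econ = zero_discount_econ
        econ.retirement_age = 0.0
        tr = make_trace(50.0, occ_pp_cycles=30)
        perm, temp = sc.permanent_and_progression_leave_cost(tr, flat_labour,
                                                             econ)
        assert perm == 0.0 and temp == 0.0

    def test_first_year_books_to_temporary_then_permanent(self, flat_labour,
                                                          zero_discount_econ):
        # progression at cycle 1, 30 post-progression cycles (~1.7 years)
        tr = make_trace(50.0, occ_pp_cycles=30)
        perm, temp = sc.permanent_and_progression_leave_cost(
            tr, flat_labour, zero_discount_econ)
        # first 17 transitions (k=0..16, (k+1)*t <= 1) are temporary
        cycles_temp = sum(1 for k in range(30) if (k + 1) * T_CYCLE <= 1.0)
        assert temp == pytest.approx(cycles_temp * 21.0, rel=1e-9)
        assert perm == pytest.approx((30 - cycles_temp) * 21.0, rel=1e-9)

    def test_capped_at_retirement_age(self, flat_labour, zero_discount_econ):
        # progression at 64.9ish: only ~0.1 years of leave fit before 65
        tr = make_trace(64.9, occ_pp_cycles=30)
        perm, temp = sc.permanent_and_progression_leave_cost(
            tr, flat_labour, zero_discount_econ)
        assert perm == 0.0
        assert 0 < temp < 0.2 * 365.25


class TestPrematureMortality:
    def test_zero_for_deaths_after_retirement(self, flat_labour,
                                              zero_discount_econ):
        tr = make_trace(68.1, death_cycle=5)
        assert sc.premature_mortality_cost(tr, flat_labour,
                                           zero_discount_econ) == 0.0

    def test_one_lost_year(self, flat_labour, zero_discount_econ):
        tr = make_trace(64.0 - T_CYCLE * 5, death_cycle=5)  # dies at 64.0
        got = sc.premature_mortality_cost(tr, flat_labour, zero_discount_econ,
                                          discounted=False)
        assert got == pytest.approx(365.25, rel=1e-9)

    def test_growth_compounds_over_lost_years(self, flat_labour):
        econ = eb.EconomicSettings()
        econ.discount_rate_annual = 0.0
        econ.productivity_growth = 0.01
        ages = range(16, 101)
        lab = sc.LabourSchedule(ages, [1.0 if a < 65 else 0.0 for a in ages],
                                [100.0] * 85)
        tr = make_trace(63.0 - T_CYCLE, death_cycle=1)  # dies at exactly 63
        got = sc.premature_mortality_cost(tr, lab, econ, discounted=False)
        e0 = 1 * T_CYCLE  # elapsed model time at the death cycle
        expected = 100 * 1.01 ** e0 + 100 * 1.01 ** (e0 + 1)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_discounting_reduces_loss(self, flat_labour):
        econ = eb.EconomicSettings()
        tr = make_trace(55.0, death_cycle=10)
        disc = sc.premature_mortality_cost(tr, flat_labour, econ,
                                           discounted=True)
        undisc = sc.premature_mortality_cost(tr, flat_labour, econ,
                                             discounted=False)
        assert 0 < disc < undisc


class TestLabourSchedule:
    def test_validation(self):
        with pytest.raises(eb.ParameterError):
            sc.LabourSchedule([16, 18], [0.5, 0.5], [1.0, 1.0])  # gap in ages
        with pytest.raises(eb.ParameterError):
            sc.LabourSchedule([16, 17], [1.5, 0.5], [1.0, 1.0])

    def test_csv_roundtrip(self, tmp_path, flat_labour):
        path = tmp_path / "lab.csv"
        flat_labour.to_csv(path)
        again = sc.LabourSchedule.from_csv(path)
        assert np.array_equal(again.employment_rate,
                              flat_labour.employment_rate)
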