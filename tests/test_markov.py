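"""Markov engine: hazards, per-cycle probabilities, traces and incidence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import eocburden as eb
from eocburden.markov import (largest_remainder, run_multi_cohort,
                              project_incidence)
from eocburden.parameters import DomainError, IncidenceSpec, STAGES
from eocburden.synthetic import generate_life_table

T_CYCLE = 21 / 365.25


class TestHazards:
    def test_rate_identity_at_ln2(self):
        assert eb.exp_rate_from_median(math.log(2)) == pytest.approx(1.0)

    @pytest.mark.parametrize("median,expected", [
        (8.33, 0.08321094604561168),
        (1.60, 0.43321698784996576),
    ])
    def test_rate_values(self, median, expected):
        assert eb.exp_rate_from_median(median) == pytest.approx(expected,
                                                                rel=1e-12)

    def test_nonpositive_median_rejected(self):
        with pytest.raises(DomainError):
            eb.exp_rate_from_median(0.0)

    def test_progression_median_identity(self):
        for me in (18.33, 6.25, 2.0, 1.6):
            assert eb.prob_progress(me, me) == pytest.approx(0.5, abs=1e-12)

    def test_progression_at_zero_time(self):
        assert eb.prob_progress(5.0, 0.0) == 0.0

    def test_progression_one_cycle_stage_iv(self):
        assert eb.prob_progress(1.6, T_CYCLE) == \
            pytest.approx(0.024600114305831533, rel=1e-12)

    def test_postprog_death_median_identity(self):
        assert eb.prob_death_postprog(1.9, 1.6, 0.3, 0.0) == \
            pytest.approx(0.5, abs=1e-12)

    def test_postprog_death_one_cycle_stage_iv(self):
        assert eb.prob_death_postprog(1.9, 1.6, T_CYCLE, 0.0) == \
            pytest.approx(0.12439600326142597, rel=1e-9)

    def test_postprog_death_capped_at_one(self):
        assert eb.prob_death_postprog(1.9, 1.6, T_CYCLE, 1.0) == 1.0

    def test_postprog_death_requires_os_above_pfs(self):
        with pytest.raises(DomainError):
            eb.prob_death_postprog(1.6, 1.6, 0.1, 0.0)

    def test_natural_death(self):
        lt = generate_life_table(a=0.0)
        assert eb.natural_death_prob(70, lt, T_CYCLE) == 0.0
        lt01 = eb.LifeTable(range(0, 101), [0.01] * 101)
        assert eb.natural_death_prob(50, lt01, 1.0) == \
            pytest.approx(0.009950166250831893, rel=1e-12)
        assert eb.natural_death_prob(50, lt01, T_CYCLE) == \
            pytest.approx(0.0005747834139857577, rel=1e-12)


class TestCycleProbabilities:
    def test_rows_sum_to_one_all_stages(self, default_params):
        for s in STAGES:
            for age in (40.0, 57.4, 68.1, 85.0, 120.0):
                probs = eb.cycle_probabilities(
                    default_params.stages[s], age, default_params.economics,
                    default_params.life_table)
                probs.validate(tol=1e-12)

    def test_zero_mortality_reduces_to_progression_only(self, default_params):
        lt = generate_life_table(a=0.0)
        probs = eb.cycle_probabilities(default_params.stages["I"], 60.0,
                                       default_params.economics, lt)
        assert probs.pdss == 0.0
        assert probs.prss == pytest.approx(1.0 - probs.ppss, abs=1e-15)


class TestCohortTrace:
    def test_entry_conditions(self, default_result):
        for tr in default_result.traces:
            assert tr.frac_stable[0] == 1.0
            assert tr.frac_dead[0] == 0.0

    def test_zero_size_cohort(self, default_params):
        tr = eb.run_cohort_trace(default_params.stages["II"], 2017, 0.0,
                                 default_params.economics,
                                 default_params.life_table)
        assert tr.size == 0.0
        tr.validate()

    def test_conservation_and_monotonicity(self, default_result):
        for tr in default_result.traces:
            tr.validate(tol=1e-9)

    def test_deterministic_bit_identical(self, default_params):
        a = eb.run_cohort_trace(default_params.stages["III"], 2018, 100,
                                default_params.economics,
                                default_params.life_table)
        b = eb.run_cohort_trace(default_params.stages["III"], 2018, 100,
                                default_params.economics,
                                default_params.life_table)
        assert np.array_equal(a.frac_stable, b.frac_stable)
        assert np.array_equal(a.new_deaths, b.new_deaths)

    def test_exponential_oracle_zero_mortality(self, default_params):
        """With natural mortality off, cumulative progression matches the
        exponential CDF exactly at every cycle boundary."""
        lt = generate_life_table(a=0.0)
        for s in STAGES:
            stage = default_params.stages[s]
            tr = eb.run_cohort_trace(stage, 2017, 1.0,
                                     default_params.economics, lt)
            cycles = np.arange(tr.frac_stable.size)
            expected = 1.0 - np.exp(-math.log(2) * cycles * T_CYCLE
                                    / stage.median_pfs)
            cum_prog = 1.0 - tr.frac_stable
            assert np.max(np.abs(cum_prog - expected)) < 1e-9

    def test_stage_iv_one_year_closed_form(self, default_params):
        lt = generate_life_table(a=0.0)
        tr = eb.run_cohort_trace(default_params.stages["IV"], 2017, 1.0,
                                 default_params.economics, lt, n_cycles=18)
        assert tr.frac_stable[18] == pytest.approx(0.6386877794272137,
                                                   abs=1e-3)

    def test_life_years_monotone_in_median_os(self, default_params):
        stage = default_params.stages["IV"]
        base = eb.run_cohort_trace(stage, 2017, 1.0, default_params.economics,
                                   default_params.life_table)
        longer = stage.__class__(**{**stage.__dict__, "median_os": 3.0})
        tr2 = eb.run_cohort_trace(longer, 2017, 1.0, default_params.economics,
                                  default_params.life_table)
        assert tr2.alive().sum() >= base.alive().sum()

    def test_stage_ordering_of_life_years(self, default_params):
        ly = {}
        for s in STAGES:
            tr = eb.run_cohort_trace(default_params.stages[s], 2017, 1.0,
                                     default_params.economics,
                                     default_params.life_table)
            ly[s] = tr.alive().sum()
        assert ly["I"] > ly["II"] > ly["III"] > ly["IV"]

    def test_postprogression_survival_subcohort(self, default_params):
        tr = eb.run_cohort_trace(default_params.stages["IV"], 2017, 1.0,
                                 default_params.economics,
                                 default_params.life_table)
        surv = tr.postprogression_survival(5)
        assert surv[0] == 1.0
        assert np.all(np.diff(surv) <= 0)


class TestIncidence:
    def test_first_year_reproduces_published_counts(self, default_params):
        proj = project_incidence(default_params.economics,
                                 default_params.incidence,
                                 default_params.stages)
        first = proj.stage_counts.iloc[0]
        assert list(first) == [1155, 195, 1116, 681]
        assert first.sum() == 3147

    def test_flat_projection_with_full_epithelial_fraction(self,
                                                           default_params):
        spec = IncidenceSpec(first_year_oc=1000, annual_increment=0,
                             epithelial_fraction=1.0)
        proj = project_incidence(default_params.economics, spec,
                                 default_params.stages)
        assert np.all(proj.stage_counts.sum(axis=1) == 1000)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(total=st.integers(1, 10_000),
           shares=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6))
    def test_largest_remainder_sums_exactly(self, total, shares):
        counts = largest_remainder(total, np.array(shares))
        assert counts.sum() == total
        assert np.all(counts >= 0)

    def test_multi_cohort_count_and_truncation(self, default_params,
                                               default_result):
        traces = default_result.traces
        assert len(traces) == 4 * 10
        cpy = default_params.economics.cycles_per_year
        for tr in traces:
            years = default_params.economics.last_year - tr.entry_year + 1
            assert tr.n_cycles == years * cpy

    def test_total_entries_conserved_under_flat_incidence(self,
                                                          default_result):
        per_year = default_result.projection.stage_counts.sum(axis=1)
        assert (per_year == per_year.iloc[0]).all()
        total = sum(tr.size for tr in default_result.traces)
        assert total == 10 * per_year.iloc[0]
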