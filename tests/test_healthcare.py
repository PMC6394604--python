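"""Direct healthcare costing: dose math, vial solver, chemo and pathways."""

import itertools
import math

import numpy as np
import pytest

import eocburden as eb
from eocburden import healthcare as hc
from eocburden.parameters import DomainError, ParameterError


class TestDoseFormulas:
    @pytest.mark.parametrize("height,weight,expected", [
        (159, 65, 1.6705805292594504),
        (160, 66, 1.6891160308501336),
        (100, 100, 1.4333964470736429),
    ])
    def test_du_bois(self, height, weight, expected):
        assert hc.bsa_du_bois(height, weight) == pytest.approx(expected,
                                                               rel=1e-9)

    def test_du_bois_rejects_degenerate(self):
        with pytest.raises(DomainError):
            hc.bsa_du_bois(0, 65)

    @pytest.mark.parametrize("auc,gfr,expected", [
        (6, 100, 750.0), (0, 80, 0.0), (5, 75, 500.0)])
    def test_calvert(self, auc, gfr, expected):
        assert hc.carboplatin_dose_calvert(auc, gfr) == expected

    def test_administration_fee(self):
        assert hc.administration_cost(0) == pytest.approx(9.60)
        assert hc.administration_cost(180) == pytest.approx(67.20)
        with pytest.raises(DomainError):
            hc.administration_cost(-1)

    def test_bevacizumab_weight_dosing(self, default_params):
        comp = [c for c in default_params.catalogue.category("advanced")
                if c.drug_id == "bevacizumab"][0]
        stage = default_params.stages["IV"]  # 66 kg
        assert hc.component_dose_mg(comp, stage, default_params.chemo) == \
            pytest.approx(15 * 66)
        low = default_params.copy()
        low.chemo.bevacizumab_dose_per_kg = 7.5
        assert hc.component_dose_mg(comp, stage, low.chemo) == \
            pytest.approx(7.5 * 66)


def brute_force_vials(dose, options):
    """Independent exhaustive oracle over all covering combinations."""
    best = math.inf
    ranges = [range(0, math.ceil(dose / mg) + 1) for mg, _ in options]
    for combo in itertools.product(*ranges):
        mg = sum(k * m for k, (m, _) in zip(combo, options))
        if mg >= dose:
            cost = sum(k * p for k, (_, p) in zip(combo, options))
            best = min(best, cost)
    return best


class TestVialSolver:
    def test_single_size_ceiling(self):
        counts, cost = hc.vials_and_drug_cost(150, [(100, 10)])
        assert counts == [2] and cost == 20

    def test_mixed_sizes_beat_ceiling(self):
        counts, cost = hc.vials_and_drug_cost(150, [(100, 10), (50, 6)])
        assert counts == [1, 1] and cost == 16

    def test_exact_fit(self):
        counts, cost = hc.vials_and_drug_cost(100, [(100, 10)])
        assert counts == [1] and cost == 10

    def test_empty_options_rejected(self):
        with pytest.raises(DomainError):
            hc.vials_and_drug_cost(100, [])

    def test_matches_exhaustive_oracle_randomised(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = rng.integers(1, 4)
            options = [(float(rng.integers(1, 12) * 25),
                        float(rng.integers(1, 200))) for _ in range(n)]
            dose = float(rng.integers(1, 1200))
            counts, cost = hc.vials_and_drug_cost(dose, options)
            assert sum(k * m for k, (m, _) in zip(counts, options)) >= dose
            assert cost == pytest.approx(brute_force_vials(dose, options))

    def test_catalogue_entries_agree_with_oracle(self, default_params):
        econ = default_params.economics
        for comp in default_params.catalogue.components:
            stage = default_params.stages["III"]
            dose = hc.component_dose_mg(comp, stage, default_params.chemo)
            options = default_params.catalogue.public_vial_options(comp, econ)
            _, cost = hc.vials_and_drug_cost(dose, options)
            assert cost == pytest.approx(brute_force_vials(dose, options))


class TestChemoCosting:
    def test_market_share_weighted_mean(self, default_params):
        params = default_params.copy()
        comps = [
            hc.DrugComponent("a", "adjuvant", "flat", 100, 0, [100.0],
                             [100.0], 0.5, deduction_applies=False),
            hc.DrugComponent("b", "adjuvant", "flat", 100, 0, [100.0],
                             [200.0], 0.5, deduction_applies=False),
        ]
        params.catalogue = hc.DrugCatalogue(comps)
        vat = params.economics.vat_drugs
        expected = 0.5 * (100 * (1 + vat) + 9.6) + 0.5 * (200 * (1 + vat)
                                                          + 9.6)
        got = hc.chemo_cycle_cost("adjuvant", params.stages["I"], params)
        assert got == pytest.approx(expected)

    def test_shares_must_sum_to_one(self):
        comps = [hc.DrugComponent("a", "adjuvant", "flat", 10, 0, [10.0],
                                  [1.0], 0.6)]
        with pytest.raises(ParameterError, match="market shares"):
            hc.DrugCatalogue(comps)

    def test_price_scale_scales_drug_cost_only(self, default_params):
        base = hc.chemo_cycle_cost("advanced", default_params.stages["IV"],
                                   default_params)
        scaled = default_params.copy()
        scaled.catalogue.price_scale = 2.0
        doubled = hc.chemo_cycle_cost("advanced", scaled.stages["IV"], scaled)
        admin = sum(c.market_share
                    * hc.administration_cost(c.infusion_minutes,
                                             default_params.economics)
                    for c in default_params.catalogue.category("advanced"))
        assert doubled == pytest.approx(2 * (base - admin) + admin)


class TestStageTreatment:
    def test_all_none_mix_costs_nothing(self, flat_cost_params):
        stage = flat_cost_params.stages["I"].__class__(
            **{**flat_cost_params.stages["I"].__dict__,
               "treatment_mix": {"none": 1.0, "surgery_only": 0.0,
                                 "neoadjuvant_plus_surgery": 0.0,
                                 "surgery_plus_adjuvant": 0.0}})
        tc = hc.stage_treatment_cost(stage, flat_cost_params)
        assert tc.total == 0.0

    def test_stage_i_surgery_is_laparotomy_plus_hysterectomy(
            self, flat_cost_params):
        cost = hc.surgery_cost_per_operated(flat_cost_params.stages["I"],
                                            flat_cost_params)
        assert cost == pytest.approx(4500 + 3800)

    def test_stage_iv_untreated_share(self, flat_cost_params):
        stage = flat_cost_params.stages["IV"]
        tc = hc.stage_treatment_cost(stage, flat_cost_params)
        full = hc.surgery_cost_per_operated(stage, flat_cost_params)
        assert tc.surgery == pytest.approx((1 - 0.088) * full)


class TestPerCycleCosts:
    def test_hospitalization_stage_iii_hand_value(self, flat_cost_params):
        hosp, er = hc.hospitalization_er_cost_per_cycle(
            flat_cost_params.stages["III"], flat_cost_params)
        semiannual = (hosp + er) * 9  # 9 cycles per half year
        assert semiannual == pytest.approx(0.482 * 2.1 * 4000
                                           + 0.222 * 1.7 * 200)

    def test_stage_i_equals_stage_ii(self, flat_cost_params):
        a = hc.hospitalization_er_cost_per_cycle(flat_cost_params.stages["I"],
                                                 flat_cost_params)
        b = hc.hospitalization_er_cost_per_cycle(flat_cost_params.stages["II"],
                                                 flat_cost_params)
        assert a == b

    def test_zero_rates_cost_nothing(self, flat_cost_params):
        stage = flat_cost_params.stages["I"].__class__(
            **{**flat_cost_params.stages["I"].__dict__,
               "pct_hospitalized": 0.0, "pct_er": 0.0})
        assert hc.hospitalization_er_cost_per_cycle(stage, flat_cost_params) \
            == (0.0, 0.0)

    def test_followup_postprogression_at_least_stable(self, flat_cost_params):
        for s in ("I", "II", "III", "IV"):
            stage = flat_cost_params.stages[s]
            assert hc.followup_cost_per_cycle("post_progression", stage,
                                              flat_cost_params) >= \
                hc.followup_cost_per_cycle("stable", stage, flat_cost_params)

    def test_empty_followup_schedule(self, flat_cost_params):
        params = flat_cost_params.copy()
        params.followup["stable"] = {}
        assert hc.followup_cost_per_cycle("stable", params.stages["I"],
                                          params) == 0.0


class TestCascadeAndPalliative:
    def test_cascade_hand_values(self, flat_cost_params):
        patient, _ = hc.genetic_cascade_cost(1000, flat_cost_params.cascade,
                                             flat_cost_params, 0.0)
        # 20% tested x (200 test + 2 x 50 visits)
        assert patient == pytest.approx(60_000)

    def test_cascade_zero_testing(self, flat_cost_params):
        params = flat_cost_params.copy()
        params.cascade.pct_tested = 0.0
        assert hc.genetic_cascade_cost(1000, params.cascade, params, 10) == \
            (0.0, 0.0)

    def test_relative_count_product(self, flat_cost_params):
        casc = flat_cost_params.cascade
        relatives = (casc.pct_tested * casc.pct_positive
                     * casc.relatives_per_positive * 1000)
        assert relatives == pytest.approx(50)

    def test_palliative_components(self, flat_cost_params):
        cost = hc.palliative_cost_per_death(flat_cost_params.palliative,
                                            flat_cost_params)
        # home-team branch and sedation contributions are additively visible
        no_home = flat_cost_params.copy()
        no_home.palliative.pct_home_team = 0.0
        no_home.palliative.pct_outpatient = 1.0
        cost2 = hc.palliative_cost_per_death(no_home.palliative, no_home)
        home_contrib = 0.067 * 9.5 * 80 - 0.067 * 6.9 * 40
        assert cost - cost2 == pytest.approx(home_contrib)
        no_sed = flat_cost_params.copy()
        no_sed.palliative.pct_sedation = 0.0
        assert cost - hc.palliative_cost_per_death(no_sed.palliative,
                                                   no_sed) == \
            pytest.approx(0.14 * 100)

    def test_palliative_linear_in_prices(self, flat_cost_params):
        doubled = flat_cost_params.copy()
        for col in ("unit_cost_min", "unit_cost", "unit_cost_max"):
            doubled.unit_costs.frame[col] *= 2
        doubled.unit_costs = eb.UnitCostTable(doubled.unit_costs.frame)
        assert hc.palliative_cost_per_death(doubled.palliative, doubled) == \
            pytest.approx(2 * hc.palliative_cost_per_death(
                flat_cost_params.palliative, flat_cost_params))


class TestExposure:
    def test_uncapped_exposure_equals_occupancy(self, default_result):
        tr = default_result.traces[3]  # a stage IV cohort
        exposure = hc.postprogression_exposure(tr, None)
        assert np.allclose(exposure, tr.frac_postprog)

    def test_capped_exposure_below_occupancy(self, default_result):
        tr = default_result.traces[3]
        capped = hc.postprogression_exposure(tr, 6)
        assert np.all(capped <= tr.frac_postprog + 1e-12)
        assert capped.sum() < tr.frac_postprog.sum()
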