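"""End-to-end model run: parameters -> Markov traces -> costing -> breakdown.

Costs accrue at cycle resolution and are discounted from the model start
(first calendar year) to the accrual cycle; calendar reporting buckets are
18-cycle blocks.  Event-linked costs (palliative pathway, formal care,
premature mortality) attach to the cycle at which the event arrives; state
membership is evaluated at cycle start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import healthcare, societal
from .markov import (CohortTrace, IncidenceProjection, project_incidence,
                     run_multi_cohort)
from .parameters import ModelParameters, STAGES
from .reporting import CostBreakdown, build_breakdown, discount


@dataclass
class StageCostCache:
    """Per-stage unit quantities reused across cohorts of one run."""

    screening_per_patient: float
    diagnosis_per_patient: float
    surgery_per_patient: float          # expected over the treatment mix
    neoadjuvant_cycle: float
    stable_regimen_cycle: float         # adjuvant (I-III) or advanced (IV)
    stable_regimen_cycles: int | None   # None = while in the stable state
    pp_regimen_cycle: float             # relapse regimen per cycle
    pp_max_cycles: int | None           # None = while post-progression
    neoadj_continues: bool              # neoadjuvant patients move on to the
                                        # stable regimen after their course
    pp_uptake: float
    hosp_per_cycle: float
    er_per_cycle: float
    followup_stable: float
    followup_pp: float
    palliative_per_death: float
    relatives_per_patient: float
    counselling_visit: float
    surveillance_halfyear: float


def _stage_cache(stage_label: str, params: ModelParameters) -> StageCostCache:
    stage = params.stages[stage_label]
    mix = stage.treatment_mix
    casc = params.cascade
    visit = params.item_cost("genetic_counselling_visit")

    if stage_label == "IV":
        stable_cat, stable_cycles = "advanced", params.chemo.advanced_max_cycles
        pp_cat, pp_cap = "advanced", params.chemo.advanced_max_cycles
    elif stage_label == "III":
        stable_cat, stable_cycles = "adjuvant", params.chemo.adjuvant_cycles
        pp_cat, pp_cap = "advanced", params.chemo.advanced_max_cycles
    else:
        stable_cat, stable_cycles = "adjuvant", params.chemo.adjuvant_cycles
        pp_cat, pp_cap = ("post_progression",
                          params.chemo.post_progression_max_cycles)

    hosp, er = healthcare.hospitalization_er_cost_per_cycle(stage, params)
    return StageCostCache(
        screening_per_patient=casc.pct_tested * (
            params.item_cost("brca_test") + casc.counselling_visits * visit),
        diagnosis_per_patient=healthcare.diagnosis_cost_per_patient(params),
        surgery_per_patient=(1.0 - mix["none"])
        * healthcare.surgery_cost_per_operated(stage, params),
        neoadjuvant_cycle=healthcare.chemo_cycle_cost("neoadjuvant", stage,
                                                      params),
        stable_regimen_cycle=healthcare.chemo_cycle_cost(stable_cat, stage,
                                                         params),
        stable_regimen_cycles=stable_cycles,
        pp_regimen_cycle=healthcare.chemo_cycle_cost(pp_cat, stage, params),
        pp_max_cycles=pp_cap,
        # at stage IV the advanced category runs in both states, so patients
        # completing the neoadjuvant course continue on it
        neoadj_continues=(stage_label == "IV"),
        pp_uptake=1.0 - mix["none"],
        hosp_per_cycle=hosp, er_per_cycle=er,
        followup_stable=healthcare.followup_cost_per_cycle("stable", stage,
                                                           params),
        followup_pp=healthcare.followup_cost_per_cycle("post_progression",
                                                       stage, params),
        palliative_per_death=healthcare.palliative_cost_per_death(
            params.palliative, params),
        relatives_per_patient=(casc.pct_tested * casc.pct_positive
                               * casc.relatives_per_positive),
        counselling_visit=visit,
        surveillance_halfyear=healthcare.relative_surveillance_halfyear_cost(
            params),
    )


def _cohort_streams(trace: CohortTrace, cache: StageCostCache,
                    params: ModelParameters) -> list:
    """Tidy cost records (stage, row, year, amount) for one cohort."""
    econ = params.economics
    r = econ.discount_rate_annual
    t = econ.cycle_years
    cpy = econ.cycles_per_year
    offset = trace.entry_year - econ.first_year
    n = trace.frac_stable.size
    size = trace.size
    stage = params.stages[trace.stage_label]
    mix = stage.treatment_mix

    cycles = np.arange(n)
    dfac = (1.0 + r) ** (-(offset + cycles * t))
    year_of = trace.entry_year + np.minimum(cycles // cpy,
                                            econ.last_year - trace.entry_year)

    rows: dict[str, np.ndarray] = {
        key: np.zeros(n) for key in
        ("screening_patients", "genetic_relatives", "diagnosis", "followup",
         "surgery", "chemotherapy", "hospitalizations", "emergency",
         "palliative", "public_formal", "private_formal")}

    # --- one-off entry costs ------------------------------------------------
    rows["screening_patients"][0] = size * cache.screening_per_patient * \
        dfac[0]
    rows["diagnosis"][0] = size * cache.diagnosis_per_patient * dfac[0]
    # neoadjuvant surgery happens after the three pre-operative cycles
    surg_now = (mix["surgery_only"] + mix["surgery_plus_adjuvant"]) \
        * healthcare.surgery_cost_per_operated(stage, params)
    surg_later = mix["neoadjuvant_plus_surgery"] \
        * healthcare.surgery_cost_per_operated(stage, params)
    rows["surgery"][0] = size * surg_now * dfac[0]
    c_surg = min(3, n - 1)
    rows["surgery"][c_surg] += size * surg_later * dfac[c_surg]

    # --- genetic cascade: relatives ------------------------------------------
    relatives = size * cache.relatives_per_patient
    rows["genetic_relatives"][0] = relatives * cache.counselling_visit * \
        dfac[0]
    max_years = min(params.surveillance_years,
                    econ.last_year - trace.entry_year + 1)
    h = 0.5
    while h <= max_years + 1e-9:
        c_idx = min(n - 1, int(h * cpy))   # nearest cycle bucket
        rows["genetic_relatives"][c_idx] += (
            relatives * cache.surveillance_halfyear
            * discount(1.0, offset + h, r))
        h += 0.5

    # --- chemotherapy ---------------------------------------------------------
    s_occ = trace.frac_stable
    chemo = np.zeros(n)
    upto = min(params.chemo.neoadjuvant_cycles, n - 1)
    chemo[:upto] += (s_occ[:upto] * mix["neoadjuvant_plus_surgery"]
                     * cache.neoadjuvant_cycle)
    upto = n - 1 if cache.stable_regimen_cycles is None \
        else min(cache.stable_regimen_cycles, n - 1)
    chemo[:upto] += (s_occ[:upto] * mix["surgery_plus_adjuvant"]
                     * cache.stable_regimen_cycle)
    if cache.neoadj_continues:
        start = min(params.chemo.neoadjuvant_cycles, n - 1)
        chemo[start:n - 1] += (s_occ[start:n - 1]
                               * mix["neoadjuvant_plus_surgery"]
                               * cache.stable_regimen_cycle)
    exposure = healthcare.postprogression_exposure(trace, cache.pp_max_cycles)
    chemo[:n - 1] += (exposure[:n - 1] * cache.pp_uptake
                      * cache.pp_regimen_cycle)
    rows["chemotherapy"] = size * chemo * dfac

    # --- per-cycle occupancy costs -------------------------------------------
    alive = trace.alive()
    rows["hospitalizations"][:n - 1] = (size * alive[:n - 1]
                                        * cache.hosp_per_cycle
                                        * dfac[:n - 1])
    rows["emergency"][:n - 1] = (size * alive[:n - 1] * cache.er_per_cycle
                                 * dfac[:n - 1])
    rows["followup"][:n - 1] = (
        size * (s_occ[:n - 1] * cache.followup_stable
                + trace.frac_postprog[:n - 1] * cache.followup_pp)
        * dfac[:n - 1])

    # --- event-linked costs ----------------------------------------------------
    deaths = size * trace.new_deaths
    rows["palliative"] = deaths * cache.palliative_per_death * dfac
    formal = societal.formal_care_cost_per_death(params.care)
    rows["public_formal"] = deaths * formal.public * dfac
    rows["private_formal"] = deaths * formal.private * dfac

    # --- assemble records -------------------------------------------------------
    records = []
    for key, amounts in rows.items():
        series = pd.Series(amounts).groupby(year_of).sum()
        for year, amount in series.items():
            records.append({"stage": trace.stage_label, "row": key,
                            "year": int(year), "amount": float(amount)})

    # societal streams (already discounted and size-scaled)
    informal = societal.informal_care_cost(
        trace, params.care, econ, window=params.informal_care_window,
        by_year=True)
    for year, amount in informal.items():
        records.append({"stage": trace.stage_label, "row": "informal",
                        "year": int(year), "amount": float(amount)})

    perm, prog_temp = societal.permanent_and_progression_leave_cost(
        trace, params.labour, econ, by_year=True)
    temp0 = societal.temporary_leave_cost(trace, params.labour, econ)
    records.append({"stage": trace.stage_label, "row": "temp_disability",
                    "year": trace.entry_year, "amount": float(temp0)})
    for year, amount in prog_temp.items():
        records.append({"stage": trace.stage_label, "row": "temp_disability",
                        "year": int(year), "amount": float(amount)})
    for year, amount in perm.items():
        records.append({"stage": trace.stage_label, "row": "perm_disability",
                        "year": int(year), "amount": float(amount)})

    premature = societal.premature_mortality_cost(
        trace, params.labour, econ,
        discounted=params.premature_mortality_discounted, by_year=True)
    for year, amount in premature.items():
        records.append({"stage": trace.stage_label,
                        "row": "premature_mortality",
                        "year": int(year), "amount": float(amount)})
    return records


def patient_denominators(traces: list, proj: IncidenceProjection,
                         params: ModelParameters) -> pd.DataFrame:
    """Patients alive at year start plus incident patients, per stage-year."""
    econ = params.economics
    cpy = econ.cycles_per_year
    years = list(proj.years)
    alive = {(s, y): 0.0 for s in STAGES for y in years}
    for tr in traces:
        for y in years:
            if y <= tr.entry_year:
                continue
            c = (y - tr.entry_year) * cpy
            if c < tr.frac_stable.size:
                alive[(tr.stage_label, y)] += tr.size * float(tr.alive()[c])
    records = []
    for s in STAGES:
        for y in years:
            incident = float(proj.stage_counts.loc[y, s])
            records.append({"stage": s, "year": y,
                            "patients": alive[(s, y)] + incident})
    return pd.DataFrame(records)


@dataclass
class ModelResult:
    """Everything one run produces."""

    params: ModelParameters
    projection: IncidenceProjection
    traces: list
    streams: pd.DataFrame
    denominators: pd.DataFrame
    breakdown: CostBreakdown

    def summary(self) -> dict:
        return self.breakdown.summary()


def run_model(params: ModelParameters) -> ModelResult:
    """Run the full pipeline on a resolved parameter registry."""
    params.validate()
    proj = project_incidence(params.economics, params.incidence, params.stages)
    traces = run_multi_cohort(params)
    caches = {s: _stage_cache(s, params) for s in STAGES}
    records = []
    for tr in traces:
        records.extend(_cohort_streams(tr, caches[tr.stage_label], params))
    streams = pd.DataFrame(records)
    denominators = patient_denominators(traces, proj, params)
    breakdown = build_breakdown(streams, denominators)
    return ModelResult(params=params, projection=proj, traces=traces,
                       streams=streams, denominators=denominators,
                       breakdown=breakdown)
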