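"""Direct healthcare costing: screening cascade, diagnosis, follow-up,
surgery, chemotherapy with explicit dose math, hospitalisations/emergencies
and the end-of-life palliative pathway.

Chemotherapy doses follow clinical dosing rules: body-surface-area dosing via
the Du Bois formula, carboplatin via the Calvert formula (target AUC x
(GFR + 25)), weight-based dosing (bevacizumab) and flat doses.  Intravenous
drugs are billed as whole vials with no sharing between patients — the solver
picks the cheapest whole-vial combination covering the dose — plus an
administration fee per infusion minute and a fixed preparation time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (DomainError, EconomicSettings, ModelParameters,
                         ParameterError, StageParameters, drug_public_price)

CHEMO_CATEGORIES = ("neoadjuvant", "adjuvant", "post_progression", "advanced")
DOSE_RULES = ("per_m2", "auc_based", "per_kg", "flat")

#: items making up the one-off diagnostic workup at entry
DIAGNOSIS_ITEMS = ("ovarian_biopsy", "biochemistry_panel",
                   "vaginal_ultrasound", "ct_scan", "ca125")

DEFAULT_FOLLOWUP_SCHEDULE = {
    # annual frequencies per alive patient, by health state
    "stable": {"oncology_visit": 3.0, "ca125": 3.0, "tvus": 1.0},
    "post_progression": {"oncology_visit": 6.0, "ca125": 6.0, "ct_scan": 2.0},
}

#: every unit-cost item the costing layer resolves
REQUIRED_UNIT_COST_ITEMS = (
    "brca_test", "genetic_counselling_visit", "tvus", "ca125",
    "ovarian_biopsy", "biochemistry_panel", "vaginal_ultrasound", "ct_scan",
    "oncology_visit",
    "laparotomy", "omentectomy", "hysterectomy", "salpingo_oophorectomy",
    "lymphadenectomy",
    "hospital_stay", "er_visit",
    "palliative_home_visit", "outpatient_nurse_visit", "primary_care_visit",
    "home_nurse_visit", "terminal_hospital_stay", "sedation_drugs",
)


# ---------------------------------------------------------------------------
# assumption blocks
# ---------------------------------------------------------------------------

@dataclass
class GeneticCascade:
    """BRCA1/2 testing cascade: tested patients, positives and their relatives.

    A fifth of incident patients are referred to testing with two counselling
    visits; 5% test positive and each positive index case brings five family
    members into counselling plus six-monthly surveillance (transvaginal
    ultrasound and a CA125 blood test).
    """

    pct_tested: float = 0.20
    counselling_visits: float = 2.0
    pct_positive: float = 0.05
    relatives_per_positive: float = 5.0

    def validate(self) -> None:
        for name in ("pct_tested", "pct_positive"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"cascade.{name} not in [0, 1]")
        if self.counselling_visits < 0 or self.relatives_per_positive < 0:
            raise ParameterError("cascade counts must be >= 0")


@dataclass
class PalliativePathway:
    """End-of-life pathway over the last 48 days of life.

    Most patients (93.3%) are followed at the outpatient hospital by a nurse
    (``outpatient_nurse_visits`` is a package default: roughly weekly over the
    48-day window); the rest receive a palliative home-care team (9.5 home
    visits).  Everyone pays four primary-care visits, spends the terminal
    phase at home (59.6%) or in hospital (40.4%), passes the last three days
    at home with two nurse visits per day, and 14% receive sedation drugs.
    """

    duration_days: float = 48.0
    pct_outpatient: float = 0.933
    pct_home_team: float = 0.067
    home_visits: float = 9.5
    outpatient_nurse_visits: float = 6.9
    primary_care_visits: float = 4.0
    pct_terminal_home: float = 0.596
    pct_terminal_hospital: float = 0.404
    terminal_home_days: float = 3.0
    nurse_visits_per_day: float = 2.0
    pct_sedation: float = 0.14

    def validate(self) -> None:
        for name in ("pct_outpatient", "pct_home_team", "pct_terminal_home",
                     "pct_terminal_hospital", "pct_sedation"):
            if not 0 <= getattr(self, name) <= 1:
                raise ParameterError(f"palliative.{name} not in [0, 1]")
        if abs(self.pct_outpatient + self.pct_home_team - 1) > 1e-6:
            raise ParameterError("palliative: outpatient/home-team split "
                                 "must sum to 1")
        if abs(self.pct_terminal_home + self.pct_terminal_hospital - 1) > 1e-6:
            raise ParameterError("palliative: terminal-location split "
                                 "must sum to 1")
        for name in ("duration_days", "home_visits", "outpatient_nurse_visits",
                     "primary_care_visits", "terminal_home_days",
                     "nurse_visits_per_day"):
            if getattr(self, name) < 0:
                raise ParameterError(f"palliative.{name} must be >= 0")


@dataclass
class ChemoSettings:
    """Dosing inputs and treatment-duration policy for chemotherapy.

    GFR is a configurable constant (no serum-creatinine source is modelled).
    ``advanced_max_cycles`` optionally caps occupancy-linked advanced
    treatment; the default (``None``) treats occupants until death or the
    horizon end, matching continuous administration of the advanced category
    in both stage IV states and post-progression at stage III.
    ``post_progression_max_cycles`` is one relapse line for early stages.
    """

    gfr_ml_min: float = 100.0
    bevacizumab_dose_per_kg: float = 15.0
    neoadjuvant_cycles: int = 6          # 3 pre-op + 3 post-op
    adjuvant_cycles: int = 6
    post_progression_max_cycles: int = 6
    advanced_max_cycles: int | None = None   # None = while occupied

    def validate(self) -> None:
        if self.gfr_ml_min < 0 or self.bevacizumab_dose_per_kg < 0:
            raise ParameterError("chemo: doses/GFR must be >= 0")
        for name in ("neoadjuvant_cycles", "adjuvant_cycles",
                     "post_progression_max_cycles", "advanced_max_cycles"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ParameterError(f"chemo.{name} must be >= 0")


# ---------------------------------------------------------------------------
# drug catalogue
# ---------------------------------------------------------------------------

@dataclass
class DrugComponent:
    """One drug within a chemotherapy category, with dosing and vial pricing."""

    drug_id: str
    category: str
    dose_rule: str
    dose_value: float            # mg/m2, AUC, mg/kg or mg depending on rule
    infusion_minutes: float
    vial_mg: list                # vial sizes (mg)
    vial_list_price: list        # ex-factory list prices (euros)
    market_share: float
    deduction_applies: bool = True

    def validate(self) -> None:
        if self.category not in CHEMO_CATEGORIES:
            raise ParameterError(f"catalogue.{self.drug_id}: bad category "
                                 f"{self.category!r}")
        if self.dose_rule not in DOSE_RULES:
            raise ParameterError(f"catalogue.{self.drug_id}: bad dose_rule")
        if self.dose_value < 0 or self.infusion_minutes < 0:
            raise ParameterError(f"catalogue.{self.drug_id}: negative dose "
                                 "or infusion time")
        if len(self.vial_mg) != len(self.vial_list_price) or not self.vial_mg:
            raise ParameterError(f"catalogue.{self.drug_id}: vial lists "
                                 "must be parallel and non-empty")
        if any(m <= 0 for m in self.vial_mg) or \
                any(p < 0 for p in self.vial_list_price):
            raise ParameterError(f"catalogue.{self.drug_id}: bad vial data")
        if not 0 <= self.market_share <= 1:
            raise ParameterError(f"catalogue.{self.drug_id}: market_share "
                                 "not in [0, 1]")


class DrugCatalogue:
    """All chemotherapy components, grouped by category.

    ``price_scale`` is a global multiplier on list prices (the manufacturer
    price sensitivity scenario).
    """

    def __init__(self, components: list, price_scale: float = 1.0):
        self.components = list(components)
        self.price_scale = float(price_scale)
        for comp in self.components:
            comp.validate()
        for cat in CHEMO_CATEGORIES:
            comps = self.category(cat)
            if comps:
                total = sum(c.market_share for c in comps)
                if abs(total - 1.0) > 1e-9:
                    raise ParameterError(
                        f"catalogue: market shares of {cat!r} sum to {total}")

    def category(self, cat: str) -> list:
        return [c for c in self.components if c.category == cat]

    def public_vial_options(self, comp: DrugComponent,
                            econ: EconomicSettings) -> list:
        """Vial options (mg, public price) after deduction, VAT and scaling."""
        ded = econ.drug_deduction_rate if comp.deduction_applies else 0.0
        return [(mg, drug_public_price(lp * self.price_scale, ded,
                                       econ.vat_drugs))
                for mg, lp in zip(comp.vial_mg, comp.vial_list_price)]

    # -- serialisation -----------------------------------------------------

    def to_records(self) -> list:
        recs = []
        for c in self.components:
            recs.append({
                "drug_id": c.drug_id, "category": c.category,
                "dose_rule": c.dose_rule, "dose_value": c.dose_value,
                "infusion_minutes": c.infusion_minutes,
                "vials": ";".join(f"{m}:{p}" for m, p in
                                  zip(c.vial_mg, c.vial_list_price)),
                "market_share": c.market_share,
                "deduction_applies": c.deduction_applies,
            })
        return recs

    @classmethod
    def from_records(cls, records: list, price_scale: float = 1.0
                     ) -> "DrugCatalogue":
        comps = []
        for r in records:
            vial_mg, vial_price = [], []
            for tok in str(r["vials"]).split(";"):
                m, p = tok.split(":")
                vial_mg.append(float(m))
                vial_price.append(float(p))
            comps.append(DrugComponent(
                drug_id=r["drug_id"], category=r["category"],
                dose_rule=r["dose_rule"], dose_value=float(r["dose_value"]),
                infusion_minutes=float(r["infusion_minutes"]),
                vial_mg=vial_mg, vial_list_price=vial_price,
                market_share=float(r["market_share"]),
                deduction_applies=bool(r.get("deduction_applies", True))))
        return cls(comps, price_scale=price_scale)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.to_records()).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DrugCatalogue":
        df = pd.read_csv(path, comment="#")
        return cls.from_records(df.to_dict(orient="records"))


# ---------------------------------------------------------------------------
# dose math
# ---------------------------------------------------------------------------

def bsa_du_bois(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m2): 0.007184 * height^0.725 * weight^0.425."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError("height and weight must be > 0")
    return 0.007184 * height_cm ** 0.725 * weight_kg ** 0.425


def carboplatin_dose_calvert(target_auc: float, gfr_ml_min: float) -> float:
    """Carboplatin dose (mg) by the Calvert formula: AUC * (GFR + 25)."""
    if target_auc < 0 or gfr_ml_min < 0:
        raise DomainError("AUC and GFR must be >= 0")
    return target_auc * (gfr_ml_min + 25.0)


def administration_cost(infusion_minutes: float,
                        econ: EconomicSettings | None = None) -> float:
    """Day-hospital administration fee: per-minute rate over infusion plus
    a fixed preparation time (defaults: 0.32 euros/min, 30 min)."""
    if infusion_minutes < 0:
        raise DomainError("infusion_minutes must be >= 0")
    per_min = econ.admin_cost_per_min if econ else 0.32
    prep = econ.admin_prep_min if econ else 30.0
    return per_min * (infusion_minutes + prep)


def vials_and_drug_cost(dose_mg: float, vial_options: list) -> tuple:
    """Cheapest whole-vial combination covering *dose_mg* (no vial sharing).

    *vial_options* is a list of ``(mg_per_vial, price_per_vial)``.  Small
    option sets are searched exhaustively (bounded branch-and-bound).
    Returns ``(counts, total_price)`` with *counts* parallel to the options.
    """
    if not vial_options:
        raise DomainError("at least one vial option is required")
    if dose_mg <= 0:
        raise DomainError("dose must be > 0")
    sizes = [float(m) for m, _ in vial_options]
    prices = [float(p) for _, p in vial_options]
    n = len(sizes)

    best_cost = math.inf
    best_counts = None

    def search(i: int, remaining: float, cost: float, counts: list) -> None:
        nonlocal best_cost, best_counts
        if cost >= best_cost:
            return
        if remaining <= 0:
            best_cost = cost
            best_counts = counts + [0] * (n - len(counts))
            return
        if i == n:
            return
        max_i = math.ceil(remaining / sizes[i])
        # try the largest count first so a feasible bound appears early
        for k in range(max_i, -1, -1):
            counts.append(k)
            search(i + 1, remaining - k * sizes[i], cost + k * prices[i],
                   counts)
            counts.pop()

    # order by price per mg so good solutions are found early
    order = sorted(range(n), key=lambda i: prices[i] / sizes[i])
    sizes = [sizes[i] for i in order]
    prices = [prices[i] for i in order]
    search(0, dose_mg, 0.0, [])

    counts = [0] * n
    for pos, i in enumerate(order):
        counts[i] = best_counts[pos]
    return counts, best_cost


def component_dose_mg(comp: DrugComponent, stage: StageParameters,
                      chemo: ChemoSettings) -> float:
    """Administered dose (mg) for one component given stage anthropometry."""
    if comp.dose_rule == "per_m2":
        bsa = bsa_du_bois(stage.mean_height, stage.mean_weight)
        return comp.dose_value * bsa
    if comp.dose_rule == "auc_based":
        return carboplatin_dose_calvert(comp.dose_value, chemo.gfr_ml_min)
    if comp.dose_rule == "per_kg":
        per_kg = (chemo.bevacizumab_dose_per_kg
                  if comp.drug_id == "bevacizumab" else comp.dose_value)
        return per_kg * stage.mean_weight
    return comp.dose_value   # flat


def component_cycle_cost(comp: DrugComponent, stage: StageParameters,
                         params: ModelParameters) -> float:
    """Drug (whole vials at public price) + administration, one cycle."""
    dose = component_dose_mg(comp, stage, params.chemo)
    options = params.catalogue.public_vial_options(comp, params.economics)
    if dose <= 0:
        drug = 0.0
    else:
        _, drug = vials_and_drug_cost(dose, options)
    return drug + administration_cost(comp.infusion_minutes, params.economics)


def chemo_cycle_cost(category: str, stage: StageParameters,
                     params: ModelParameters) -> float:
    """Market-share-weighted expected cost of one cycle of a category."""
    comps = params.catalogue.category(category)
    if not comps:
        raise ParameterError(f"catalogue: no components for {category!r}")
    return sum(c.market_share * component_cycle_cost(c, stage, params)
               for c in comps)


# ---------------------------------------------------------------------------
# per-stage, per-event and per-cycle costs
# ---------------------------------------------------------------------------

@dataclass
class TreatmentCost:
    """Expected initial-treatment cost per incident patient."""

    surgery: float
    chemotherapy: float

    @property
    def total(self) -> float:
        return self.surgery + self.chemotherapy


def surgery_cost_per_operated(stage: StageParameters,
                              params: ModelParameters) -> float:
    """Expected procedure cost of one operated patient (surgery mix)."""
    return sum(frac * params.item_cost(proc)
               for proc, frac in stage.surgery_mix.items())


def stage_treatment_cost(stage: StageParameters,
                         params: ModelParameters) -> TreatmentCost:
    """Expected initial-treatment cost per patient over the four pathways.

    Surgery applies to every pathway except "none".  Neoadjuvant patients
    receive six cycles (three before and three after surgery) of the
    neoadjuvant regimen; adjuvant patients receive the adjuvant regimen at
    stages I-III, and the advanced regimen at stage IV (where chemotherapy
    given in either state belongs to the advanced category).
    """
    mix = stage.treatment_mix
    operated = 1.0 - mix["none"]
    surgery = operated * surgery_cost_per_operated(stage, params)

    chemo = 0.0
    if mix["neoadjuvant_plus_surgery"] > 0:
        chemo += (mix["neoadjuvant_plus_surgery"]
                  * params.chemo.neoadjuvant_cycles
                  * chemo_cycle_cost("neoadjuvant", stage, params))
    if mix["surgery_plus_adjuvant"] > 0:
        cat = "advanced" if stage.stage_label == "IV" else "adjuvant"
        chemo += (mix["surgery_plus_adjuvant"] * params.chemo.adjuvant_cycles
                  * chemo_cycle_cost(cat, stage, params))
    return TreatmentCost(surgery=surgery, chemotherapy=chemo)


def hospitalization_er_cost_per_cycle(stage: StageParameters,
                                      params: ModelParameters) -> tuple:
    """(hospitalisation, emergency) euros per alive patient per cycle.

    Published rates are semi-annual expectations; a half year spans
    ``cycles_per_year / 2`` cycles.
    """
    cycles_per_6mo = params.economics.cycles_per_year / 2.0
    hosp = (stage.pct_hospitalized * stage.hosp_per_6mo
            * params.item_cost("hospital_stay")) / cycles_per_6mo
    er = (stage.pct_er * stage.er_per_6mo
          * params.item_cost("er_visit")) / cycles_per_6mo
    return hosp, er


def genetic_cascade_cost(eoc_patients: float, cascade: GeneticCascade,
                         params: ModelParameters,
                         years_of_surveillance: float) -> tuple:
    """(patient-side, relatives-side) euros for a group of incident patients.

    Patient side: BRCA test plus counselling visits for the tested share.
    Relatives side: counselling plus six-monthly surveillance (TVUS + CA125)
    for the cascade of relatives of test-positive patients.  Undiscounted;
    the pipeline spreads the surveillance stream over time itself.
    """
    if eoc_patients < 0 or years_of_surveillance < 0:
        raise DomainError("counts must be >= 0")
    visit = params.item_cost("genetic_counselling_visit")
    patient_side = cascade.pct_tested * eoc_patients * (
        params.item_cost("brca_test") + cascade.counselling_visits * visit)
    relatives = (cascade.pct_tested * cascade.pct_positive
                 * cascade.relatives_per_positive * eoc_patients)
    surveillance = relative_surveillance_halfyear_cost(params)
    relatives_side = relatives * (visit + 2.0 * years_of_surveillance
                                  * surveillance)
    return patient_side, relatives_side


def relative_surveillance_halfyear_cost(params: ModelParameters) -> float:
    """One six-monthly surveillance round for a relative (TVUS + CA125)."""
    return params.item_cost("tvus") + params.item_cost("ca125")


def diagnosis_cost_per_patient(params: ModelParameters) -> float:
    """One-off diagnostic workup at entry."""
    return sum(params.item_cost(i) for i in DIAGNOSIS_ITEMS)


def palliative_cost_per_death(pathway: PalliativePathway,
                              params: ModelParameters) -> float:
    """Expected palliative-pathway cost per dying patient."""
    pathway.validate()
    c = params.item_cost
    cost = pathway.pct_home_team * pathway.home_visits * \
        c("palliative_home_visit")
    cost += pathway.pct_outpatient * pathway.outpatient_nurse_visits * \
        c("outpatient_nurse_visit")
    cost += pathway.primary_care_visits * c("primary_care_visit")
    cost += pathway.pct_terminal_hospital * c("terminal_hospital_stay")
    cost += (pathway.terminal_home_days * pathway.nurse_visits_per_day
             * c("home_nurse_visit"))
    cost += pathway.pct_sedation * c("sedation_drugs")
    return cost


def followup_cost_per_cycle(state: str, stage: StageParameters,
                            params: ModelParameters) -> float:
    """Per-cycle follow-up cost of one patient in *state*.

    The schedule gives annual visit/test frequencies per state; the per-cycle
    cost is the annual expectation scaled by the cycle length.
    """
    if state not in params.followup:
        raise ParameterError(f"followup: unknown state {state!r}")
    schedule = params.followup[state]
    annual = sum(freq * params.item_cost(item)
                 for item, freq in schedule.items())
    return annual * params.economics.cycle_years


# ---------------------------------------------------------------------------
# occupancy-linked chemotherapy exposure
# ---------------------------------------------------------------------------

def postprogression_exposure(trace, max_cycles: int | None) -> np.ndarray:
    """Expected occupancy still within *max_cycles* of its progression.

    Element *c* sums, over progression cycles ``c0 <= c`` with
    ``c - c0 < max_cycles``, the surviving fraction of each progression
    sub-cohort — the patients eligible for relapse treatment at cycle *c*.
    ``max_cycles=None`` means uncapped: the whole post-progression occupancy.
    """
    n = trace.frac_stable.size
    if max_cycles is None:
        return trace.frac_postprog.copy()
    out = np.zeros(n)
    new_prog = trace.new_progressions
    for c0 in range(1, n):
        if new_prog[c0] <= 0:
            continue
        surv = trace.postprogression_survival(c0)
        upto = min(max_cycles, surv.size, n - c0)
        out[c0:c0 + upto] += new_prog[c0] * surv[:upto]
    return out
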