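"""Synthetic stand-ins for inputs that are not published in the open tables:
regional unit costs, the chemotherapy drug catalogue, the female life table
and the age-specific labour schedule — plus verbatim fixtures of the two
published tables (stage-level inputs and the model results matrix) used for
aggregation-layer verification.

Every generated value is a labelled placeholder of realistic Spanish-context
magnitude, never a real tariff.  Generation is deterministic per seed; CSVs
written by :func:`write_fixture_bundle` carry a provenance header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .healthcare import DrugCatalogue, DrugComponent
from .parameters import (LifeTable, ParameterError, UnitCostTable,
                         default_stage_parameters, STAGES)
from .reporting import ROW_KEYS, CostBreakdown
from .societal import LabourSchedule

# ---------------------------------------------------------------------------
# unit costs (emulating the unpublished regional tariff tables)
# ---------------------------------------------------------------------------

#: item -> (description, unit, plausible median euro value)
_UNIT_COST_BASE = {
    "brca_test": ("BRCA1/2 germline panel", "per-test", 600.0),
    "genetic_counselling_visit": ("Genetic counselling visit", "per-visit",
                                  90.0),
    "tvus": ("Transvaginal ultrasound", "per-test", 62.0),
    "ca125": ("CA125 tumour-marker blood test", "per-test", 24.0),
    "ovarian_biopsy": ("Ovarian biopsy", "per-test", 480.0),
    "biochemistry_panel": ("Biochemical analysis", "per-test", 32.0),
    "vaginal_ultrasound": ("Vaginal ultrasonography", "per-test", 60.0),
    "ct_scan": ("Abdominopelvic CT scan", "per-test", 140.0),
    "oncology_visit": ("Oncology outpatient visit", "per-visit", 110.0),
    "laparotomy": ("Exploratory laparotomy", "per-procedure", 4500.0),
    "omentectomy": ("Omentectomy", "per-procedure", 1900.0),
    "hysterectomy": ("Abdominal total hysterectomy", "per-procedure", 3900.0),
    "salpingo_oophorectomy": ("Bilateral salpingo-oophorectomy",
                              "per-procedure", 2600.0),
    "lymphadenectomy": ("Pelvic/para-aortic lymphadenectomy",
                        "per-procedure", 2300.0),
    "hospital_stay": ("Oncology hospitalization (per stay)", "per-stay",
                      4300.0),
    "er_visit": ("Emergency department visit", "per-visit", 190.0),
    "palliative_home_visit": ("Palliative home-care team visit", "per-visit",
                              85.0),
    "outpatient_nurse_visit": ("Outpatient palliative nurse visit",
                               "per-visit", 42.0),
    "primary_care_visit": ("Primary-care doctor visit", "per-visit", 55.0),
    "home_nurse_visit": ("Home nurse visit", "per-visit", 46.0),
    "terminal_hospital_stay": ("Terminal-phase hospital stay", "per-stay",
                               3600.0),
    "sedation_drugs": ("Palliative sedation drugs", "per-treatment", 110.0),
}


def generate_unit_costs(seed: int = 0) -> UnitCostTable:
    """Deterministic synthetic unit-cost table with min/median/max columns.

    Medians are jittered around documented plausible magnitudes; the min and
    max columns emulate the spread of regional tariffs.  Source years are
    spread over 2014-2016; 2016 tariffs are marked already-actualised
    (CPI category ``none``).
    """
    rng = np.random.default_rng(int(seed))
    rows = []
    for item_id, (desc, unit, base) in _UNIT_COST_BASE.items():
        median = base * rng.uniform(0.92, 1.08)
        lo = median * rng.uniform(0.60, 0.90)
        hi = median * rng.uniform(1.15, 1.60)
        source_year = int(rng.choice([2014, 2015, 2016]))
        cpi = "none" if source_year == 2016 else "medicine"
        rows.append({"item_id": item_id, "description": desc, "unit": unit,
                     "unit_cost_min": round(lo, 2),
                     "unit_cost": round(median, 2),
                     "unit_cost_max": round(hi, 2),
                     "source_year": source_year, "cpi_category": cpi})
    return UnitCostTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# drug catalogue (emulating the unpublished dosing/pricing tables)
# ---------------------------------------------------------------------------

# drug: dose rule, per-cycle dose, infusion minutes, vials (mg, list euros),
# statutory-deduction flag (True for on-patent products)
_DRUGS = {
    "paclitaxel": ("per_m2", 175.0, 180.0, [(30, 55.0), (100, 150.0),
                                            (300, 390.0)], False),
    "carboplatin": ("auc_based", 5.0, 60.0, [(150, 25.0), (450, 70.0),
                                             (600, 90.0)], False),
    "doxorubicin": ("per_m2", 40.0, 60.0, [(20, 420.0), (50, 920.0)], True),
    "bevacizumab": ("per_kg", 15.0, 90.0, [(100, 310.0), (400, 1150.0)],
                    True),
    "cisplatin": ("per_m2", 75.0, 120.0, [(50, 20.0), (100, 36.0)], False),
    "gemcitabine": ("per_m2", 1000.0, 30.0, [(200, 14.0), (1000, 48.0),
                                             (2000, 90.0)], False),
    "topotecan": ("per_m2", 4.0, 30.0, [(1, 78.0), (4, 255.0)], True),
    "trabectedin": ("per_m2", 1.1, 180.0, [(0.25, 360.0), (1, 1320.0)], True),
    "docetaxel": ("per_m2", 75.0, 60.0, [(20, 58.0), (80, 185.0)], False),
}

# category -> {drug: market share}; shares within a category sum to 1
_CATEGORY_SHARES = {
    "neoadjuvant": {"paclitaxel": 0.5, "carboplatin": 0.5},
    "adjuvant": {"paclitaxel": 0.35, "carboplatin": 0.45,
                 "docetaxel": 0.10, "cisplatin": 0.10},
    "post_progression": {"carboplatin": 0.30, "paclitaxel": 0.25,
                         "gemcitabine": 0.20, "doxorubicin": 0.15,
                         "topotecan": 0.10},
    "advanced": {"bevacizumab": 0.30, "paclitaxel": 0.20, "carboplatin": 0.20,
                 "doxorubicin": 0.10, "gemcitabine": 0.08, "topotecan": 0.06,
                 "trabectedin": 0.04, "cisplatin": 0.02},
}


def generate_drug_catalogue(seed: int = 0) -> DrugCatalogue:
    """Synthetic chemotherapy catalogue: label doses, jittered list prices.

    Dose rules and per-cycle doses follow product labels (paclitaxel
    175 mg/m2, carboplatin AUC 5-6, bevacizumab 15 mg/kg, ...); list prices
    are jittered placeholders.  Carboplatin targets AUC 6 in the adjuvant and
    neoadjuvant settings and AUC 5 in relapse settings.
    """
    rng = np.random.default_rng(int(seed) + 1)
    jitter = {d: rng.uniform(0.9, 1.1) for d in _DRUGS}
    comps = []
    for cat, shares in _CATEGORY_SHARES.items():
        for drug, share in shares.items():
            rule, dose, minutes, vials, branded = _DRUGS[drug]
            if drug == "carboplatin":
                dose = 6.0 if cat in ("neoadjuvant", "adjuvant") else 5.0
            comps.append(DrugComponent(
                drug_id=drug, category=cat, dose_rule=rule, dose_value=dose,
                infusion_minutes=minutes,
                vial_mg=[float(m) for m, _ in vials],
                vial_list_price=[round(p * jitter[drug], 2)
                                 for _, p in vials],
                market_share=share, deduction_applies=branded))
    return DrugCatalogue(comps)


# ---------------------------------------------------------------------------
# life table and labour schedule
# ---------------------------------------------------------------------------

def generate_life_table(a: float = 7e-6, b: float = 0.105,
                        max_age: int = 100) -> LifeTable:
    """Gompertz female life table: rate(age) = a * exp(b * age), ages 0..max.

    Defaults approximate contemporary Spanish female all-cause mortality
    (about 4 per 1000 at age 60, 5% at 85).  ``a = 0`` yields an immortal
    test table.
    """
    if a < 0 or b < 0:
        raise ParameterError("life table parameters must be >= 0")
    if a > 0 and b == 0:
        raise ParameterError("Gompertz slope must be > 0 when a > 0")
    ages = np.arange(0, max_age + 1)
    rates = a * np.exp(b * ages)
    return LifeTable(ages, rates)


def generate_labour_schedule(seed: int = 0, retirement_age: int = 65
                             ) -> LabourSchedule:
    """Synthetic female employment rates and gross annual wages by age.

    A plateau of ~60% employment through the core working ages tapering to
    zero at the retirement age, and a wage profile rising to a mid-career
    plateau around 23k euros/year.  Deterministic per seed.
    """
    rng = np.random.default_rng(int(seed) + 2)
    ages = np.arange(16, 101)
    emp = np.zeros(ages.size)
    wage = np.zeros(ages.size)
    for i, age in enumerate(ages):
        if age >= retirement_age:
            continue
        if age < 25:
            base_emp, base_wage = 0.30, 14000.0
        elif age < 55:
            base_emp, base_wage = 0.62, 23000.0
        else:
            # taper towards retirement
            frac = (retirement_age - age) / (retirement_age - 55)
            base_emp = 0.25 + 0.30 * frac
            base_wage = 22000.0
        emp[i] = min(1.0, base_emp * rng.uniform(0.95, 1.05))
        wage[i] = base_wage * rng.uniform(0.95, 1.05)
    return LabourSchedule(ages, emp, wage)


# ---------------------------------------------------------------------------
# verbatim published-table fixtures
# ---------------------------------------------------------------------------

def stage_inputs_fixture() -> dict:
    """The published stage-level input table, as stage parameter objects."""
    return default_stage_parameters()


# Published results matrix, cells verbatim (euros; percentages and averages
# as printed).  The stage IV hospitalizations total is printed with an
# anomalous separator ("315.441.267") in the source table; it is normalised
# here to 315,441,267, which is consistent with the printed stage IV direct
# healthcare subtotal.
_RESULTS_MATRIX_CELLS = {
    # row: {stage: (total_eur, pct_of_stage, avg_annual_per_patient)}
    "screening_patients": {
        "I": (3_088_335, 0.66, 88.90), "II": (519_790, 0.45, 92.46),
        "III": (2_984_717, 0.23, 103.10), "IV": (2_569_116, 0.21, 119.03)},
    "genetic_relatives": {
        "I": (1_477_440, 0.32, 26.63), "II": (248_570, 0.21, 28.78),
        "III": (1_427_697, 0.11, 35.33), "IV": (1_105_642, 0.09, 35.09)},
    "diagnosis": {
        "I": (6_845_283, 1.46, 197.04), "II": (1_152_114, 0.99, 204.94),
        "III": (15_650_937, 1.23, 540.63), "IV": (13_471_654, 1.08, 624.17)},
    "followup": {
        "I": (12_550_184, 2.68, 230.70), "II": (2_448_326, 2.10, 288.28),
        "III": (16_131_636, 1.27, 414.67), "IV": (7_449_071, 0.60, 260.89)},
    "surgery": {
        "I": (33_386_327, 7.12, 794.29), "II": (9_138_573, 7.84, 1550.41),
        "III": (87_624_527, 6.89, 2879.72),
        "IV": (73_843_438, 5.93, 3211.65)},
    "chemotherapy": {
        "I": (73_429_456, 15.66, 1399.93), "II": (28_018_052, 24.02, 3517.86),
        "III": (223_313_473, 17.57, 6274.45),
        "IV": (725_107_595, 58.21, 23527.41)},
    "hospitalizations": {
        "I": (104_089_546, 22.20, 1915.55),
        "II": (15_453_906, 13.25, 1879.60),
        "III": (377_473_449, 29.69, 10199.17),
        "IV": (315_441_267, 25.32, 10197.08)},
    "emergency": {
        "I": (6_240_086, 1.33, 114.84), "II": (926_449, 0.79, 112.68),
        "III": (4_249_286, 0.33, 114.81), "IV": (3_550_979, 0.29, 114.79)},
    "palliative": {
        "I": (4_793_722, 1.02, 76.47), "II": (1_912_383, 1.64, 203.48),
        "III": (21_116_270, 1.66, 515.37), "IV": (10_077_388, 0.81, 527.30)},
    "public_formal": {
        "I": (126_432, 0.03, 1.99), "II": (50_370, 0.04, 5.30),
        "III": (553_693, 0.04, 13.39), "IV": (259_010, 0.02, 13.33)},
    "private_formal": {
        "I": (1_235_043, 0.26, 19.45), "II": (492_033, 0.42, 51.74),
        "III": (5_408_711, 0.43, 130.82), "IV": (2_530_115, 0.20, 130.23)},
    "informal": {
        "I": (112_708_919, 24.04, 1784.14),
        "II": (47_855_777, 41.03, 5049.87),
        "III": (505_313_452, 39.75, 12293.17),
        "IV": (90_186_328, 7.24, 3785.87)},
    "temp_disability": {
        "I": (37_936_056, 8.09, 973.23), "II": (4_136_727, 3.55, 668.13),
        "III": (9_975_732, 0.78, 342.54), "IV": (0, 0.0, 0.0)},
    "perm_disability": {
        "I": (6_129_363, 1.31, 102.23), "II": (773_669, 0.66, 94.37),
        "III": (0, 0.0, 0.0), "IV": (0, 0.0, 0.0)},
    "premature_mortality": {
        "I": (64_769_698, 13.82, 915.14), "II": (3_496_382, 3.00, 435.63),
        "III": (10_774, 0.0, 0.38), "IV": (0, 0.0, 0.0)},
}

# printed subtotal/total cells, for verification against recomputed sums
RESULTS_MATRIX_PRINTED_SUBTOTALS = {
    "DHC": {"I": (245_900_380, 52.45, 4844.35),
            "II": (59_818_164, 51.29, 7878.49),
            "III": (749_971_992, 59.00, 21077.26),
            "IV": (1_152_616_149, 92.54, 38617.41)},
    "DNHC": {"I": (114_070_394, 24.33, 1805.58),
             "II": (48_398_180, 41.50, 5106.91),
             "III": (511_275_856, 40.22, 12437.38),
             "IV": (92_975_453, 7.46, 3929.43)},
    "IC": {"I": (108_835_116, 23.22, 1990.61),
           "II": (8_406_778, 7.21, 1198.13),
           "III": (9_986_506, 0.79, 342.92),
           "IV": (0, 0.00, 0.0)},
    "Total": {"I": (468_805_889, 100.0, 8640.53),
              "II": (116_623_122, 100.0, 14183.54),
              "III": (1_271_234_354, 100.0, 33857.56),
              "IV": (1_245_591_602, 100.0, 42546.84)},
}


def results_matrix_fixture() -> CostBreakdown:
    """The published results matrix as a :class:`CostBreakdown`.

    Used only to verify the aggregation layer (subtotals, shares, headline
    sums); never fed back into the model as an input.
    """
    totals = pd.DataFrame(
        {s: [float(_RESULTS_MATRIX_CELLS[k][s][0]) for k in ROW_KEYS]
         for s in STAGES}, index=list(ROW_KEYS))
    avg = pd.DataFrame(
        {s: [float(_RESULTS_MATRIX_CELLS[k][s][2]) for k in ROW_KEYS]
         for s in STAGES}, index=list(ROW_KEYS))
    return CostBreakdown(totals=totals, avg_per_patient=avg,
                         meta={"source": "published results matrix, verbatim"})


def results_matrix_printed_pct() -> pd.DataFrame:
    """The printed percentage-of-stage cells (for cross-checks)."""
    return pd.DataFrame(
        {s: [float(_RESULTS_MATRIX_CELLS[k][s][1]) for k in ROW_KEYS]
         for s in STAGES}, index=list(ROW_KEYS))


# ---------------------------------------------------------------------------
# fixture bundle export
# ---------------------------------------------------------------------------

def write_fixture_bundle(out_dir, seed: int = 0) -> list:
    """Write every synthetic table as CSV with a provenance header.

    Returns the list of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = (f"# synthetic placeholder values - eocburden {_version}, "
              f"seed={seed}; not real tariffs\n")
    written = []

    def _write(name, frame):
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
        written.append(path)

    _write("unit_costs.csv", generate_unit_costs(seed).frame)
    _write("drug_catalogue.csv",
           pd.DataFrame(generate_drug_catalogue(seed).to_records()))
    _write("life_table.csv", generate_life_table().to_frame())
    _write("labour_schedule.csv", generate_labour_schedule(seed).to_frame())
    return written
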