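import pandas as pd
import pytest

import eocburden as eb


@pytest.fixture(scope="session")
def default_params() -> eb.ModelParameters:
    return eb.load_parameters()


@pytest.fixture(scope="session")
def default_result(default_params) -> eb.ModelResult:
    """One full default run shared by read-only tests."""
    return eb.run_model(default_params)


@pytest.fixture(scope="session")
def short_params() -> eb.ModelParameters:
    """Three-year horizon for tests that rerun the pipeline many times."""
    params = eb.load_parameters()
    params.economics.horizon_years = 3
    return params


@pytest.fixture()
def flat_unit_costs() -> eb.UnitCostTable:
    """Unit costs with known round values (base-year euros, no CPI)."""
    from eocburden.healthcare import REQUIRED_UNIT_COST_ITEMS
    values = {
        "brca_test": 200.0, "genetic_counselling_visit": 50.0,
        "tvus": 60.0, "ca125": 25.0,
        "ovarian_biopsy": 500.0, "biochemistry_panel": 30.0,
        "vaginal_ultrasound": 60.0, "ct_scan": 140.0,
        "oncology_visit": 100.0,
        "laparotomy": 4500.0, "omentectomy": 1800.0, "hysterectomy": 3800.0,
        "salpingo_oophorectomy": 2500.0, "lymphadenectomy": 2200.0,
        "hospital_stay": 4000.0, "er_visit": 200.0,
        "palliative_home_visit": 80.0, "outpatient_nurse_visit": 40.0,
        "primary_care_visit": 55.0, "home_nurse_visit": 45.0,
        "terminal_hospital_stay": 3500.0, "sedation_drugs": 100.0,
    }
    units = {"hospital_stay": "per-stay", "terminal_hospital_stay": "per-stay",
             "sedation_drugs": "per-treatment"}
    rows = []
    for item in REQUIRED_UNIT_COST_ITEMS:
        v = values[item]
        rows.append({"item_id": item, "description": item,
                     "unit": units.get(item, "per-visit"),
                     "unit_cost_min": v, "unit_cost": v, "unit_cost_max": v,
                     "source_year": 2016, "cpi_category": "none"})
    return eb.UnitCostTable(pd.DataFrame(rows))


@pytest.fixture()
def flat_cost_params(default_params, flat_unit_costs) -> eb.ModelParameters:
    params = default_params.copy()
    params.unit_costs = flat_unit_costs
    return params
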