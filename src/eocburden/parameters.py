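"""Model parameters: loading, validation and price normalisation.

Everything the model consumes is collected in a single :class:`ModelParameters`
registry: stage-level epidemiology and treatment mixes, economic settings
(discounting, CPI updating, VAT and statutory drug deductions), the unit-cost
table, the chemotherapy catalogue, the female life table, the labour schedule
and the care/palliative/genetic-cascade assumptions.  Defaults reproduce the
published stage-level inputs; a YAML config can override any subset.

All monetary amounts are euros of the base year (2016) after CPI updating.
"""

from __future__ import annotations

import copy
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

STAGES = ("I", "II", "III", "IV")

TREATMENT_PATHWAYS = ("none", "surgery_only", "neoadjuvant_plus_surgery",
                      "surgery_plus_adjuvant")
SURGERY_PROCEDURES = ("laparotomy", "omentectomy", "hysterectomy",
                      "salpingo_oophorectomy", "lymphadenectomy")
CPI_CATEGORIES = ("medicine", "general", "none")


class ParameterError(ValueError):
    """Config did not validate; the message names the offending field."""


class DomainError(ValueError):
    """A value is outside the model's mathematical domain."""


# ---------------------------------------------------------------------------
# economic settings
# ---------------------------------------------------------------------------

@dataclass
class EconomicSettings:
    """Discounting, inflation and timing constants.

    ``cycle_days`` is the Markov cycle (one chemotherapy cycle, 21 days);
    a reporting "year" is ``cycles_per_year`` = ceil(365.25/21) = 18 cycles,
    with the ~13-day residual absorbed by the last bucket.
    """

    discount_rate_annual: float = 0.03
    medicine_cpi: float = 0.0077
    general_cpi: float = 0.0197
    productivity_growth: float = 0.01
    vat_drugs: float = 0.04
    drug_deduction_rate: float = 0.075
    base_year: int = 2016
    first_year: int = 2017
    horizon_years: int = 10
    cycle_days: float = 21.0
    retirement_age: float = 65.0
    admin_cost_per_min: float = 0.32
    admin_prep_min: float = 30.0

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    @property
    def cycles_per_year(self) -> int:
        return math.ceil(365.25 / self.cycle_days)

    @property
    def last_year(self) -> int:
        return self.first_year + self.horizon_years - 1

    def validate(self) -> None:
        for name in ("discount_rate_annual", "medicine_cpi", "general_cpi",
                     "productivity_growth", "vat_drugs", "drug_deduction_rate"):
            if getattr(self, name) < 0:
                raise ParameterError(f"economics.{name} must be >= 0")
        if self.drug_deduction_rate >= 1 or self.vat_drugs >= 1:
            raise ParameterError("economics: deduction/VAT rates must be < 1")
        if self.horizon_years <= 0:
            raise ParameterError("economics.horizon_years must be > 0")
        if not 0 < self.cycle_days <= 366:
            raise ParameterError("economics.cycle_days out of range")


# ---------------------------------------------------------------------------
# stage-level parameters
# ---------------------------------------------------------------------------

@dataclass
class StageParameters:
    """Epidemiology, survival medians and treatment mix for one FIGO stage."""

    stage_label: str
    incidence_count: float
    incidence_share: float
    median_pfs: float          # years
    median_os: float           # years
    mean_age_dx: float         # years
    mean_weight: float         # kg
    mean_height: float         # cm
    hosp_per_6mo: float
    pct_hospitalized: float
    er_per_6mo: float
    pct_er: float
    treatment_mix: dict = field(default_factory=dict)
    surgery_mix: dict = field(default_factory=dict)

    def validate(self) -> None:
        lbl = f"stages.{self.stage_label}"
        if self.stage_label not in STAGES:
            raise ParameterError(f"{lbl}: unknown stage label")
        if self.median_pfs <= 0:
            raise DomainError(f"{lbl}.median_pfs must be > 0")
        if self.median_os <= self.median_pfs:
            raise DomainError(
                f"{lbl}: median_os ({self.median_os}) must exceed "
                f"median_pfs ({self.median_pfs})")
        if self.incidence_count < 0:
            raise ParameterError(f"{lbl}.incidence_count must be >= 0")
        for name in ("incidence_share", "pct_hospitalized", "pct_er"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{lbl}.{name} must be in [0, 1]")
        if set(self.treatment_mix) != set(TREATMENT_PATHWAYS):
            raise ParameterError(f"{lbl}.treatment_mix keys must be "
                                 f"{TREATMENT_PATHWAYS}")
        for k, v in self.treatment_mix.items():
            if not 0 <= v <= 1:
                raise ParameterError(f"{lbl}.treatment_mix.{k} not in [0, 1]")
        # published mixes are printed to 0.1%; accept that rounding residual
        if abs(sum(self.treatment_mix.values()) - 1.0) > 2e-3:
            raise ParameterError(f"{lbl}.treatment_mix must sum to 1")
        if set(self.surgery_mix) != set(SURGERY_PROCEDURES):
            raise ParameterError(f"{lbl}.surgery_mix keys must be "
                                 f"{SURGERY_PROCEDURES}")
        for k, v in self.surgery_mix.items():
            if not 0 <= v <= 1:
                raise ParameterError(f"{lbl}.surgery_mix.{k} not in [0, 1]")


# ---------------------------------------------------------------------------
# life table
# ---------------------------------------------------------------------------

class LifeTable:
    """Female annual all-cause mortality rates by integer age.

    Lookup clamps to the closest tabulated age, so attained ages beyond the
    table reuse the oldest rate rather than extrapolating.
    """

    def __init__(self, ages: Iterable[int], rates: Iterable[float]):
        self.ages = np.asarray(list(ages), dtype=int)
        self.rates = np.asarray(list(rates), dtype=float)
        if self.ages.size == 0:
            raise ParameterError("life_table: empty")
        if np.any(np.diff(self.ages) != 1):
            raise ParameterError("life_table: ages must be contiguous")
        if np.any(self.rates < 0):
            raise ParameterError("life_table: rates must be >= 0")

    def annual_rate(self, age: float) -> float:
        """Annual mortality rate at the integer (floored) age, clamped."""
        idx = int(np.clip(math.floor(age) - self.ages[0], 0,
                          self.ages.size - 1))
        return float(self.rates[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages,
                             "annual_mortality_rate": self.rates})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        return cls(df["age"], df["annual_mortality_rate"])


# ---------------------------------------------------------------------------
# unit costs
# ---------------------------------------------------------------------------

#: units treated as "tests and medical visits" by the min/max price scenario
TEST_VISIT_UNITS = ("per-visit", "per-test")


class UnitCostTable:
    """Priced resource items with regional min/median/max and a source year.

    Costs are resolved through :meth:`cost`, which applies CPI updating to the
    base year and honours the active price column (median by default; the
    sensitivity module switches visit/test items to the min or max column).
    """

    COLUMNS = ("item_id", "description", "unit", "unit_cost_min", "unit_cost",
               "unit_cost_max", "source_year", "cpi_category")

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ParameterError(f"unit_costs: missing columns {sorted(missing)}")
        if frame["item_id"].duplicated().any():
            dup = frame.loc[frame["item_id"].duplicated(), "item_id"].iloc[0]
            raise ParameterError(f"unit_costs: duplicate item_id {dup!r}")
        bad = ~frame["cpi_category"].isin(CPI_CATEGORIES)
        if bad.any():
            raise ParameterError("unit_costs: invalid cpi_category "
                                 f"{frame.loc[bad, 'cpi_category'].iloc[0]!r}")
        for col in ("unit_cost_min", "unit_cost", "unit_cost_max"):
            if (frame[col] < 0).any():
                raise ParameterError(f"unit_costs.{col} must be >= 0")
        self.frame = frame.reset_index(drop=True)
        self._by_id = self.frame.set_index("item_id")

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id.index

    @property
    def item_ids(self) -> list:
        return list(self.frame["item_id"])

    def cost(self, item_id: str, econ: EconomicSettings,
             test_visit_column: str = "unit_cost") -> float:
        """2016-euro cost of one unit of *item_id*."""
        try:
            row = self._by_id.loc[item_id]
        except KeyError:
            raise ParameterError(f"unit_costs: unknown item_id {item_id!r}")
        col = "unit_cost"
        if row["unit"] in TEST_VISIT_UNITS:
            col = test_visit_column
        return inflate_to_base_year(float(row[col]), int(row["source_year"]),
                                    str(row["cpi_category"]), econ)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "UnitCostTable":
        return cls(pd.read_csv(path, comment="#"))


# ---------------------------------------------------------------------------
# price normalisation
# ---------------------------------------------------------------------------

def inflate_to_base_year(amount: float, source_year: int, cpi_category: str,
                         settings: EconomicSettings) -> float:
    """Update a historical price to base-year euros by compound CPI.

    ``medicine`` uses the medicine CPI (direct healthcare items), ``general``
    the general CPI (non-healthcare items); ``none`` marks tariffs already
    expressed in base-year euros.
    """
    if amount < 0:
        raise DomainError("amount must be >= 0")
    if source_year > settings.base_year:
        raise DomainError("source_year must not exceed the base year")
    if cpi_category == "none":
        return amount
    if cpi_category == "medicine":
        rate = settings.medicine_cpi
    elif cpi_category == "general":
        rate = settings.general_cpi
    else:
        raise ParameterError(f"unknown cpi_category {cpi_category!r}")
    return amount * (1.0 + rate) ** (settings.base_year - source_year)


def drug_public_price(list_price: float, deduction_rate: float,
                      vat: float) -> float:
    """Ex-factory list price -> public price: statutory deduction, then VAT."""
    if list_price < 0 or deduction_rate < 0 or vat < 0:
        raise DomainError("price and rates must be >= 0")
    if deduction_rate >= 1 or vat >= 1:
        raise DomainError("rates must be < 1")
    return list_price * (1.0 - deduction_rate) * (1.0 + vat)


# ---------------------------------------------------------------------------
# defaults (published stage-level inputs)
# ---------------------------------------------------------------------------

_STAGE_DEFAULTS = {
    "I": dict(incidence_count=1155, incidence_share=0.37,
              median_pfs=18.33, median_os=19.50, mean_age_dx=57.4,
              mean_weight=65.0, mean_height=159.0,
              hosp_per_6mo=1.2, pct_hospitalized=0.154,
              er_per_6mo=1.5, pct_er=0.231,
              treatment_mix={"none": 0.0, "surgery_only": 0.667,
                             "neoadjuvant_plus_surgery": 0.0,
                             "surgery_plus_adjuvant": 0.333},
              surgery_mix={"laparotomy": 1.0, "omentectomy": 0.0,
                           "hysterectomy": 1.0,
                           "salpingo_oophorectomy": 0.0,
                           "lymphadenectomy": 0.0}),
    "II": dict(incidence_count=195, incidence_share=0.06,
               median_pfs=6.25, median_os=7.50, mean_age_dx=62.4,
               mean_weight=67.0, mean_height=160.0,
               hosp_per_6mo=1.2, pct_hospitalized=0.154,
               er_per_6mo=1.5, pct_er=0.231,
               treatment_mix={"none": 0.0, "surgery_only": 0.198,
                              "neoadjuvant_plus_surgery": 0.0,
                              "surgery_plus_adjuvant": 0.802},
               surgery_mix={"laparotomy": 1.0, "omentectomy": 0.0638,
                            "hysterectomy": 1.0,
                            "salpingo_oophorectomy": 1.0,
                            "lymphadenectomy": 0.0}),
    "III": dict(incidence_count=1116, incidence_share=0.35,
                median_pfs=2.00, median_os=3.20, mean_age_dx=64.9,
                mean_weight=65.0, mean_height=159.0,
                hosp_per_6mo=2.1, pct_hospitalized=0.482,
                er_per_6mo=1.7, pct_er=0.222,
                treatment_mix={"none": 0.031, "surgery_only": 0.113,
                               "neoadjuvant_plus_surgery": 0.144,
                               "surgery_plus_adjuvant": 0.711},
                surgery_mix={"laparotomy": 1.0, "omentectomy": 1.0,
                             "hysterectomy": 1.0,
                             "salpingo_oophorectomy": 1.0,
                             "lymphadenectomy": 0.75}),
    "IV": dict(incidence_count=681, incidence_share=0.22,
               median_pfs=1.60, median_os=1.90, mean_age_dx=68.1,
               mean_weight=66.0, mean_height=160.0,
               hosp_per_6mo=2.1, pct_hospitalized=0.482,
               er_per_6mo=1.7, pct_er=0.222,
               treatment_mix={"none": 0.088, "surgery_only": 0.088,
                              "neoadjuvant_plus_surgery": 0.242,
                              "surgery_plus_adjuvant": 0.582},
               surgery_mix={"laparotomy": 1.0, "omentectomy": 1.0,
                            "hysterectomy": 1.0,
                            "salpingo_oophorectomy": 1.0,
                            "lymphadenectomy": 1.0}),
}


def default_stage_parameters() -> dict:
    """The four published stage parameter sets, freshly constructed."""
    return {s: StageParameters(stage_label=s, **copy.deepcopy(d))
            for s, d in _STAGE_DEFAULTS.items()}


# ---------------------------------------------------------------------------
# incidence projection spec
# ---------------------------------------------------------------------------

@dataclass
class IncidenceSpec:
    """Linear incidence projector over the model horizon.

    ``first_year_oc`` is the all-ovarian-cancer incidence in the first model
    year; ``annual_increment`` the linear yearly change.  The epithelial
    fraction and the fixed stage split convert it to stage-level entries.
    """

    first_year_oc: float = 3497.0
    annual_increment: float = 0.0
    epithelial_fraction: float = 0.90
    rounding: str = "largest_remainder"   # or "fractional"

    def validate(self) -> None:
        if self.first_year_oc < 0:
            raise ParameterError("incidence.first_year_oc must be >= 0")
        if not 0 <= self.epithelial_fraction <= 1:
            raise ParameterError("incidence.epithelial_fraction not in [0, 1]")
        if self.rounding not in ("largest_remainder", "fractional"):
            raise ParameterError("incidence.rounding must be "
                                 "'largest_remainder' or 'fractional'")


# ---------------------------------------------------------------------------
# assembled registry
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    """Fully-resolved parameter registry for one model run."""

    economics: EconomicSettings
    stages: dict                      # stage label -> StageParameters
    incidence: IncidenceSpec
    life_table: LifeTable
    unit_costs: UnitCostTable
    catalogue: "object"               # healthcare.DrugCatalogue
    care: "object"                    # societal.CareAssumptions
    labour: "object"                  # societal.LabourSchedule
    cascade: "object"                 # healthcare.GeneticCascade
    palliative: "object"              # healthcare.PalliativePathway
    chemo: "object"                   # healthcare.ChemoSettings
    followup: dict = field(default_factory=dict)
    surveillance_years: float = 10.0
    test_visit_cost_column: str = "unit_cost"
    informal_care_window: str = "post_progression"
    premature_mortality_discounted: bool = True
    half_cycle_correction: bool = False
    seed: int = 0

    def validate(self) -> None:
        self.economics.validate()
        if set(self.stages) != set(STAGES):
            raise ParameterError("stages must cover I, II, III, IV")
        for sp in self.stages.values():
            sp.validate()
        self.incidence.validate()
        for obj in (self.care, self.cascade, self.palliative, self.chemo):
            obj.validate()
        if self.test_visit_cost_column not in ("unit_cost", "unit_cost_min",
                                               "unit_cost_max"):
            raise ParameterError("test_visit_cost_column invalid")
        if self.informal_care_window not in ("last_48_days", "post_progression",
                                             "whole_disease"):
            raise ParameterError("informal_care_window invalid")

    def item_cost(self, item_id: str) -> float:
        """Resolve a unit cost in base-year euros under the active column."""
        return self.unit_costs.cost(item_id, self.economics,
                                    self.test_visit_cost_column)

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "economics": dataclasses.asdict(self.economics),
            "stages": {s: {k: v for k, v in dataclasses.asdict(sp).items()
                           if k != "stage_label"}
                       for s, sp in self.stages.items()},
            "incidence": dataclasses.asdict(self.incidence),
            "care": dataclasses.asdict(self.care),
            "cascade": dataclasses.asdict(self.cascade),
            "palliative": dataclasses.asdict(self.palliative),
            "chemo": dataclasses.asdict(self.chemo),
            "followup": copy.deepcopy(self.followup),
            "surveillance_years": self.surveillance_years,
            "test_visit_cost_column": self.test_visit_cost_column,
            "informal_care_window": self.informal_care_window,
            "premature_mortality_discounted":
                self.premature_mortality_discounted,
            "half_cycle_correction": self.half_cycle_correction,
            "labour": self.labour.to_records(),
            "life_table": {"age": self.life_table.ages.tolist(),
                           "annual_mortality_rate":
                               self.life_table.rates.tolist()},
            "unit_costs": self.unit_costs.frame.to_dict(orient="records"),
            "catalogue": self.catalogue.to_records(),
        }
        return d


# ---------------------------------------------------------------------------
# config loading
# ---------------------------------------------------------------------------

_SCALAR_SECTIONS = ("surveillance_years", "test_visit_cost_column",
                    "informal_care_window", "premature_mortality_discounted",
                    "half_cycle_correction", "seed")


def _apply_overrides(obj, section: dict, prefix: str) -> None:
    for key, value in section.items():
        if not hasattr(obj, key):
            raise ParameterError(f"{prefix}.{key}: unknown field")
        current = getattr(obj, key)
        if isinstance(current, dict) and isinstance(value, dict):
            merged = dict(current)
            for k in value:
                if k not in merged:
                    raise ParameterError(f"{prefix}.{key}.{k}: unknown key")
            merged.update(value)
            setattr(obj, key, merged)
        else:
            setattr(obj, key, value)


def load_parameters(config_path: Optional[str] = None) -> ModelParameters:
    """Build a fully-resolved :class:`ModelParameters`.

    With no config every field takes its documented default and the synthetic
    tables are generated from the config seed (default 0).  A YAML config may
    override any subset; unknown fields raise :class:`ParameterError` naming
    the field, and domain violations (e.g. a stage with median OS below median
    PFS) raise :class:`DomainError`.
    """
    from . import healthcare, societal, synthetic

    cfg: dict = {}
    if config_path is not None:
        path = Path(config_path)
        if not path.exists():
            raise ParameterError(f"config file not found: {path}")
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParameterError("config root must be a mapping")
        cfg = loaded

    known = {"economics", "stages", "incidence", "care", "cascade",
             "palliative", "chemo", "followup", "labour", "life_table",
             "unit_costs", "catalogue", *_SCALAR_SECTIONS}
    for key in cfg:
        if key not in known:
            raise ParameterError(f"{key}: unknown config section")

    seed = int(cfg.get("seed", 0))

    econ = EconomicSettings()
    _apply_overrides(econ, cfg.get("economics", {}), "economics")

    stages = default_stage_parameters()
    for label, overrides in cfg.get("stages", {}).items():
        if label not in stages:
            raise ParameterError(f"stages.{label}: unknown stage")
        _apply_overrides(stages[label], overrides, f"stages.{label}")

    incidence = IncidenceSpec()
    _apply_overrides(incidence, cfg.get("incidence", {}), "incidence")

    care = societal.CareAssumptions()
    _apply_overrides(care, cfg.get("care", {}), "care")

    cascade = healthcare.GeneticCascade()
    _apply_overrides(cascade, cfg.get("cascade", {}), "cascade")

    palliative = healthcare.PalliativePathway()
    _apply_overrides(palliative, cfg.get("palliative", {}), "palliative")

    chemo = healthcare.ChemoSettings()
    _apply_overrides(chemo, cfg.get("chemo", {}), "chemo")

    followup = copy.deepcopy(healthcare.DEFAULT_FOLLOWUP_SCHEDULE)
    for state, sched in cfg.get("followup", {}).items():
        if state not in followup:
            raise ParameterError(f"followup.{state}: unknown state")
        followup[state] = dict(sched)

    if "life_table" in cfg:
        lt_cfg = cfg["life_table"]
        if isinstance(lt_cfg, str):
            life_table = LifeTable.from_csv(lt_cfg)
        else:
            life_table = LifeTable(lt_cfg["age"],
                                   lt_cfg["annual_mortality_rate"])
    else:
        life_table = synthetic.generate_life_table()

    if "unit_costs" in cfg:
        uc = cfg["unit_costs"]
        unit_costs = (UnitCostTable.from_csv(uc) if isinstance(uc, str)
                      else UnitCostTable(pd.DataFrame(uc)))
    else:
        unit_costs = synthetic.generate_unit_costs(seed)

    if "catalogue" in cfg:
        cat = cfg["catalogue"]
        catalogue = (healthcare.DrugCatalogue.from_csv(cat)
                     if isinstance(cat, str)
                     else healthcare.DrugCatalogue.from_records(cat))
    else:
        catalogue = synthetic.generate_drug_catalogue(seed)

    if "labour" in cfg:
        lab = cfg["labour"]
        labour = (societal.LabourSchedule.from_csv(lab) if isinstance(lab, str)
                  else societal.LabourSchedule.from_records(lab))
    else:
        labour = synthetic.generate_labour_schedule(seed)

    params = ModelParameters(
        economics=econ, stages=stages, incidence=incidence,
        life_table=life_table, unit_costs=unit_costs, catalogue=catalogue,
        care=care, labour=labour, cascade=cascade, palliative=palliative,
        chemo=chemo, followup=followup,
        surveillance_years=float(cfg.get("surveillance_years", 10.0)),
        test_visit_cost_column=cfg.get("test_visit_cost_column", "unit_cost"),
        informal_care_window=cfg.get("informal_care_window",
                                     "post_progression"),
        premature_mortality_discounted=bool(
            cfg.get("premature_mortality_discounted", True)),
        half_cycle_correction=bool(cfg.get("half_cycle_correction", False)),
        seed=seed,
    )
    params.validate()
    # referential integrity: every item the costing layer uses must resolve
    for item in healthcare.REQUIRED_UNIT_COST_ITEMS:
        if item not in params.unit_costs:
            raise ParameterError(f"unit_costs: missing required item {item!r}")
    return params
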