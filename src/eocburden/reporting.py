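"""Aggregation and reporting: discounting, the stage x category cost matrix,
per-patient annual averages and share decompositions.

The central object is :class:`CostBreakdown`: fifteen cost rows (nine direct
healthcare, three direct non-healthcare, three indirect) by the four FIGO
stages, carrying already-discounted totals and average annual costs per
patient.  Subtotals and shares are always recomputed from the row cells,
never stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import DomainError, ParameterError, STAGES

#: (row key, cost type, display label) in table order
ROWS = (
    ("screening_patients", "DHC", "Opportunistic screening test (patients)"),
    ("genetic_relatives", "DHC", "Genetic counselling (relatives)"),
    ("diagnosis", "DHC", "Diagnosis"),
    ("followup", "DHC", "Follow-up visits and tests"),
    ("surgery", "DHC", "Surgery"),
    ("chemotherapy", "DHC", "Chemotherapy"),
    ("hospitalizations", "DHC", "Hospitalizations"),
    ("emergency", "DHC", "Emergency services"),
    ("palliative", "DHC", "Palliative care"),
    ("public_formal", "DNHC", "Public formal care"),
    ("private_formal", "DNHC", "Private formal care"),
    ("informal", "DNHC", "Informal care"),
    ("temp_disability", "IC", "Temporary disability"),
    ("perm_disability", "IC", "Permanent disability"),
    ("premature_mortality", "IC", "Premature mortality"),
)

ROW_KEYS = tuple(r[0] for r in ROWS)
ROW_TYPE = {r[0]: r[1] for r in ROWS}
ROW_LABEL = {r[0]: r[2] for r in ROWS}
COST_TYPES = ("DHC", "DNHC", "IC")


def discount(amount: float, elapsed: float, rate: float) -> float:
    """Present value of *amount* accrued *elapsed* years after model start."""
    if rate < 0:
        raise DomainError("discount rate must be >= 0")
    return amount * (1.0 + rate) ** (-elapsed)


def average_annual_cost_per_patient(year_cost: float,
                                    alive_at_year_start: float,
                                    incident_in_year: float) -> float:
    """Yearly cost divided by patients alive at year start plus incident."""
    denom = alive_at_year_start + incident_in_year
    if denom <= 0:
        raise DomainError("patient denominator must be > 0")
    return year_cost / denom


@dataclass
class CostBreakdown:
    """Stage x row cost matrix with per-patient annual averages.

    ``totals`` and ``avg_per_patient`` are DataFrames indexed by the fifteen
    row keys with one column per stage.  Subtotals, percentages and shares
    are derived on demand.
    """

    totals: pd.DataFrame
    avg_per_patient: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for df in (self.totals, self.avg_per_patient):
            if list(df.index) != list(ROW_KEYS):
                missing = [r for r in ROW_KEYS if r not in df.index]
                raise ParameterError(f"breakdown missing rows: {missing}")
            if list(df.columns) != list(STAGES):
                raise ParameterError("breakdown columns must be the stages")
        if (self.totals.values < 0).any():
            raise DomainError("negative cost cell")

    # -- derived quantities --------------------------------------------------

    def stage_total(self, stage: str) -> float:
        return float(self.totals[stage].sum())

    @property
    def grand_total(self) -> float:
        return float(self.totals.values.sum())

    def category_totals(self) -> pd.DataFrame:
        """Cost-type subtotals (DHC/DNHC/IC) by stage."""
        types = pd.Series({k: ROW_TYPE[k] for k in ROW_KEYS})
        return self.totals.groupby(types).sum().reindex(list(COST_TYPES))

    def pct_of_stage(self) -> pd.DataFrame:
        """Each cell as a percentage of its stage total."""
        stage_tot = self.totals.sum(axis=0)
        return 100.0 * self.totals / stage_tot

    def category_avg_per_patient(self) -> pd.DataFrame:
        types = pd.Series({k: ROW_TYPE[k] for k in ROW_KEYS})
        return (self.avg_per_patient.groupby(types).sum()
                .reindex(list(COST_TYPES)))

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        # averages are not additive; only valid when denominators coincide,
        # which holds for disjoint row-wise splits of one run
        return CostBreakdown(totals=self.totals + other.totals,
                             avg_per_patient=(self.avg_per_patient
                                              + other.avg_per_patient))

    # -- exports --------------------------------------------------------------

    def to_table_frame(self) -> pd.DataFrame:
        """Display table: rows + subtotals, totals / % of stage / averages."""
        pct = self.pct_of_stage()
        blocks = []
        for ctype in COST_TYPES:
            keys = [k for k in ROW_KEYS if ROW_TYPE[k] == ctype]
            for k in keys:
                rec = {"row": ROW_LABEL[k], "cost_type": ctype}
                for s in STAGES:
                    rec[f"total_{s}"] = round(self.totals.loc[k, s])
                    rec[f"pct_{s}"] = round(pct.loc[k, s], 2)
                    rec[f"avg_{s}"] = round(self.avg_per_patient.loc[k, s], 2)
                blocks.append(rec)
            sub_t = self.category_totals().loc[ctype]
            sub_a = self.category_avg_per_patient().loc[ctype]
            rec = {"row": f"Total {ctype}", "cost_type": ctype}
            for s in STAGES:
                rec[f"total_{s}"] = round(sub_t[s])
                rec[f"pct_{s}"] = round(100 * sub_t[s] / self.stage_total(s), 2)
                rec[f"avg_{s}"] = round(sub_a[s], 2)
            blocks.append(rec)
        rec = {"row": "Total", "cost_type": ""}
        for s in STAGES:
            rec[f"total_{s}"] = round(self.stage_total(s))
            rec[f"pct_{s}"] = 100.0
            rec[f"avg_{s}"] = round(self.avg_per_patient[s].sum(), 2)
        blocks.append(rec)
        return pd.DataFrame(blocks)

    def to_long_frame(self) -> pd.DataFrame:
        pct = self.pct_of_stage()
        recs = []
        for k in ROW_KEYS:
            for s in STAGES:
                recs.append({"stage": s, "row": k, "cost_type": ROW_TYPE[k],
                             "total_eur": self.totals.loc[k, s],
                             "pct_of_stage": pct.loc[k, s],
                             "avg_annual_per_patient_eur":
                                 self.avg_per_patient.loc[k, s]})
        return pd.DataFrame(recs)

    def stacked_bar_frame(self) -> pd.DataFrame:
        """Cost-type composition by stage (stacked-bar dataset)."""
        cat = self.category_totals()
        recs = []
        for s in STAGES:
            for ctype in COST_TYPES:
                recs.append({"stage": s, "cost_type": ctype,
                             "total_eur": cat.loc[ctype, s],
                             "pct_of_stage":
                                 100 * cat.loc[ctype, s] / self.stage_total(s)})
        return pd.DataFrame(recs)

    def summary(self) -> dict:
        shares = decompose_shares(self)
        out = {
            "grand_total_eur": self.grand_total,
            "grand_total_mill_eur": self.grand_total / 1e6,
            "stage_totals_eur": {s: self.stage_total(s) for s in STAGES},
            **shares,
        }
        out.update({k: v for k, v in self.meta.items()})
        return out

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


def build_breakdown(streams: pd.DataFrame,
                    denominators: pd.DataFrame) -> CostBreakdown:
    """Aggregate tidy cost streams into a :class:`CostBreakdown`.

    *streams* has columns ``stage, row, year, amount`` (already discounted);
    *denominators* has columns ``stage, year, patients`` (alive at year start
    plus incident).  The average annual cost per patient of a row is the mean
    over reporting years of the yearly cost divided by that year's patient
    denominator.
    """
    required = {"stage", "row", "year", "amount"}
    if not required <= set(streams.columns):
        raise ParameterError(f"streams must have columns {sorted(required)}")
    present = set(streams["row"].unique())
    missing = [r for r in ROW_KEYS if r not in present]
    if missing:
        raise ParameterError(f"missing cost streams for rows: {missing}")
    unknown = present - set(ROW_KEYS)
    if unknown:
        raise ParameterError(f"unknown cost rows: {sorted(unknown)}")

    totals = (streams.pivot_table(index="row", columns="stage",
                                  values="amount", aggfunc="sum",
                                  fill_value=0.0)
              .reindex(index=list(ROW_KEYS), columns=list(STAGES),
                       fill_value=0.0))

    denom = denominators.set_index(["stage", "year"])["patients"]
    yearly = (streams.groupby(["stage", "row", "year"])["amount"].sum())
    avg = pd.DataFrame(0.0, index=list(ROW_KEYS), columns=list(STAGES))
    for s in STAGES:
        years = denominators.loc[denominators["stage"] == s, "year"]
        for k in ROW_KEYS:
            ratios = []
            for y in years:
                d = denom.loc[(s, y)]
                amt = yearly.get((s, k, y), 0.0)
                ratios.append(average_annual_cost_per_patient(amt, 0.0, d))
            avg.loc[k, s] = float(np.mean(ratios)) if ratios else 0.0

    # overall average annual cost per patient across stages
    tot_by_year = streams.groupby("year")["amount"].sum()
    den_by_year = denominators.groupby("year")["patients"].sum()
    overall = float(np.mean([
        average_annual_cost_per_patient(tot_by_year.get(y, 0.0), 0.0, d)
        for y, d in den_by_year.items()]))
    stage_avg = {}
    for s in STAGES:
        sub = streams[streams["stage"] == s].groupby("year")["amount"].sum()
        dsub = denominators[denominators["stage"] == s].set_index("year")[
            "patients"]
        stage_avg[s] = float(np.mean([
            average_annual_cost_per_patient(sub.get(y, 0.0), 0.0, d)
            for y, d in dsub.items()]))

    meta = {"avg_annual_cost_per_patient_eur": overall,
            "stage_avg_annual_cost_per_patient_eur": stage_avg}
    return CostBreakdown(totals=totals, avg_per_patient=avg, meta=meta)


def decompose_shares(breakdown: CostBreakdown) -> dict:
    """Cost-type, stage and indirect-cost share decompositions (percent)."""
    grand = breakdown.grand_total
    if grand <= 0:
        raise DomainError("grand total must be > 0 to decompose shares")
    cat = breakdown.category_totals().sum(axis=1)
    ic_rows = breakdown.totals.loc[
        ["temp_disability", "perm_disability", "premature_mortality"]
    ].sum(axis=1)
    ic_total = float(ic_rows.sum())
    dnhc_total = float(cat["DNHC"])
    informal = float(breakdown.totals.loc["informal"].sum())
    return {
        "cost_type_shares_pct": {c: 100 * float(cat[c]) / grand
                                 for c in COST_TYPES},
        "stage_shares_pct": {s: 100 * breakdown.stage_total(s) / grand
                             for s in STAGES},
        "ic_split_pct": {
            "temporary": 100 * float(ic_rows["temp_disability"]) / ic_total
            if ic_total else 0.0,
            "permanent": 100 * float(ic_rows["perm_disability"]) / ic_total
            if ic_total else 0.0,
            "premature_mortality":
                100 * float(ic_rows["premature_mortality"]) / ic_total
            if ic_total else 0.0,
        },
        "informal_share_of_dnhc_pct":
            100 * informal / dnhc_total if dnhc_total else 0.0,
    }
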