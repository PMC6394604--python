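"""Deterministic one-way sensitivity analysis and tornado extraction.

A scenario names one or more parameters in the registry (dotted paths, with
``*`` ranging over the stages) and either sets or scales them, once for the
low bound and once for the high bound; single-sided scenarios leave the high
bound at the base case.  The tornado dataset reruns the full pipeline per
bound and ranks scenarios by the width of the total-burden range.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .parameters import ModelParameters, ParameterError
from .pipeline import run_model


@dataclass
class Change:
    """One parameter perturbation: set a value or scale the current one."""

    path: str
    op: str              # "set" or "scale"
    value: float | str

    def validate(self) -> None:
        if self.op not in ("set", "scale"):
            raise ParameterError(f"scenario op must be set/scale, got "
                                 f"{self.op!r}")
        if self.op == "scale" and not isinstance(self.value, (int, float)):
            raise ParameterError("scale factor must be numeric")
        if self.op == "scale" and self.value <= 0:
            raise ParameterError("scale factor must be > 0")


@dataclass
class ScenarioSpec:
    """A named one-way scenario with low and (optionally) high bounds."""

    name: str
    low: list = field(default_factory=list)
    high: list | None = None

    def to_dict(self) -> dict:
        enc = lambda chs: [{"path": c.path, "op": c.op, "value": c.value}
                           for c in chs]
        return {"name": self.name, "low": enc(self.low),
                "high": enc(self.high) if self.high is not None else None}

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        dec = lambda chs: [Change(**c) for c in chs]
        return cls(name=d["name"], low=dec(d["low"]),
                   high=dec(d["high"]) if d.get("high") else None)


def _targets(params: ModelParameters, path: str) -> list:
    """Resolve a dotted path to (container, attribute/key) pairs."""
    parts = path.split(".")
    nodes = [params]
    for part in parts[:-1]:
        nxt = []
        for node in nodes:
            if part == "*":
                if isinstance(node, dict):
                    nxt.extend(node.values())
                else:
                    raise ParameterError(f"{path}: '*' needs a mapping")
            elif isinstance(node, dict):
                if part not in node:
                    raise ParameterError(f"{path}: unknown key {part!r}")
                nxt.append(node[part])
            else:
                if not hasattr(node, part):
                    raise ParameterError(f"{path}: unknown field {part!r}")
                nxt.append(getattr(node, part))
        nodes = nxt
    leaf = parts[-1]
    out = []
    for node in nodes:
        if isinstance(node, dict):
            if leaf not in node:
                raise ParameterError(f"{path}: unknown key {leaf!r}")
        elif not hasattr(node, leaf):
            raise ParameterError(f"{path}: unknown field {leaf!r}")
        out.append((node, leaf))
    return out


def apply_scenario(params: ModelParameters,
                   changes: list) -> ModelParameters:
    """Return a deep, independent copy of *params* with *changes* applied."""
    new = copy.deepcopy(params)
    for ch in changes:
        ch.validate()
        for node, leaf in _targets(new, ch.path):
            current = node[leaf] if isinstance(node, dict) else \
                getattr(node, leaf)
            value = ch.value if ch.op == "set" else current * ch.value
            if isinstance(node, dict):
                node[leaf] = value
            else:
                setattr(node, leaf, value)
    new.validate()
    return new


def default_scenario_suite() -> list:
    """The ten standard one-way scenarios.

    Note the genetic-counselling scenario range (35-70%) sits above the 20%
    base case; both are kept as published.
    """
    S, C = ScenarioSpec, Change
    return [
        S("genetic_counselling_pct",
          low=[C("cascade.pct_tested", "set", 0.35)],
          high=[C("cascade.pct_tested", "set", 0.70)]),
        S("patient_weight",
          low=[C("stages.*.mean_weight", "scale", 0.9)],
          high=[C("stages.*.mean_weight", "scale", 1.1)]),
        S("productivity_growth",
          low=[C("economics.productivity_growth", "set", 0.0)],
          high=[C("economics.productivity_growth", "set", 0.02)]),
        S("drug_price",
          low=[C("catalogue.price_scale", "scale", 0.9)]),
        S("drug_deduction_rate",
          low=[C("economics.drug_deduction_rate", "set", 0.0)],
          high=[C("economics.drug_deduction_rate", "set", 0.06)]),
        S("test_visit_prices",
          low=[C("test_visit_cost_column", "set", "unit_cost_min")],
          high=[C("test_visit_cost_column", "set", "unit_cost_max")]),
        S("age_at_diagnosis",
          low=[C("stages.*.mean_age_dx", "scale", 0.9)],
          high=[C("stages.*.mean_age_dx", "scale", 1.1)]),
        S("bevacizumab_dose",
          low=[C("chemo.bevacizumab_dose_per_kg", "set", 7.5)]),
        S("caregiver_wage",
          low=[C("care.wage_per_hour", "set", 7.5)]),
        S("informal_care_hours",
          low=[C("care.hours_informal", "scale", 0.7)],
          high=[C("care.hours_informal", "scale", 1.3)]),
    ]


def run_tornado(params: ModelParameters, suite: list) -> pd.DataFrame:
    """Total burden and average annual cost per patient for every scenario.

    Returns one row per scenario with the low/high outputs, sorted by the
    width of the total-burden range (widest first; names break ties).  The
    base-case outputs are attached as frame attrs.
    """
    if not suite:
        raise ParameterError("scenario suite is empty")
    base = run_model(params)
    base_total = base.breakdown.grand_total
    base_avg = base.summary()["avg_annual_cost_per_patient_eur"]

    rows = []
    for spec in suite:
        lo = run_model(apply_scenario(params, spec.low))
        lo_total = lo.breakdown.grand_total
        lo_avg = lo.summary()["avg_annual_cost_per_patient_eur"]
        if spec.high is not None:
            hi = run_model(apply_scenario(params, spec.high))
            hi_total = hi.breakdown.grand_total
            hi_avg = hi.summary()["avg_annual_cost_per_patient_eur"]
        else:
            hi_total, hi_avg = base_total, base_avg
        rows.append({"scenario": spec.name,
                     "low_total": lo_total, "high_total": hi_total,
                     "low_avg": lo_avg, "high_avg": hi_avg,
                     "range_total": abs(hi_total - lo_total)})
    df = pd.DataFrame(rows).sort_values(
        ["range_total", "scenario"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    df.attrs["base_total"] = base_total
    df.attrs["base_avg"] = base_avg
    return df


def load_scenario_suite(path) -> list:
    """Read a scenario suite from a YAML or JSON file."""
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    data = yaml.safe_load(text) if not str(path).endswith(".json") \
        else json.loads(text)
    if not isinstance(data, list):
        raise ParameterError("scenario suite file must contain a list")
    return [ScenarioSpec.from_dict(d) for d in data]


def save_scenario_suite(suite: list, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump([s.to_dict() for s in suite], fh, sort_keys=False)
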