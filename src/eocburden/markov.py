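"""Three-state Markov cohort engine (stable / post-progression / dead).

Patients enter in the *stable* state at diagnosis.  Each 21-day cycle they
remain stable, progress, or die; progressed patients remain post-progression
until death.  Progression and post-progression death hazards come from
exponential survival curves fitted to the stage's median PFS and median OS
(the post-progression hazard uses the median OS minus median PFS gap), and
natural mortality comes from the female life table at the attained age:

    Ppss(t) = 1 - exp(-t * ln2 / me_PFS)
    Pdps(t) = 1 - exp(-t * ln2 / (me_OS - me_PFS)) + Pnd

The engine is a deterministic expected-value evaluation: no Monte Carlo,
identical inputs give bit-identical traces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (DomainError, EconomicSettings, IncidenceSpec,
                         LifeTable, ModelParameters, StageParameters, STAGES)

log = logging.getLogger(__name__)

LN2 = math.log(2.0)


# ---------------------------------------------------------------------------
# hazards and per-cycle probabilities
# ---------------------------------------------------------------------------

def exp_rate_from_median(median: float) -> float:
    """Exponential hazard (per year) implied by a median survival time."""
    if median <= 0:
        raise DomainError("median must be > 0")
    return LN2 / median


def prob_progress(median_pfs: float, t: float) -> float:
    """Probability of progressing within *t* years, exponential PFS curve."""
    if median_pfs <= 0:
        raise DomainError("median_pfs must be > 0")
    if t < 0:
        raise DomainError("t must be >= 0")
    return 1.0 - math.exp(-exp_rate_from_median(median_pfs) * t)


def prob_death_postprog(median_os: float, median_pfs: float, t: float,
                        pnd: float) -> float:
    """Probability of dying within *t* years in the post-progression state.

    The disease hazard uses the exponential curve through the median
    post-progression survival (median OS minus median PFS); the natural
    death probability *pnd* is added and the result capped at 1.
    """
    if median_os <= median_pfs:
        raise DomainError("median_os must exceed median_pfs")
    if not 0.0 <= pnd <= 1.0:
        raise DomainError("pnd must be in [0, 1]")
    if t < 0:
        raise DomainError("t must be >= 0")
    rate = LN2 / (median_os - median_pfs)
    return min(1.0, 1.0 - math.exp(-rate * t) + pnd)


def natural_death_prob(attained_age: float, life_table: LifeTable,
                       t: float) -> float:
    """Probability of general-population death within *t* years at an age."""
    if t < 0:
        raise DomainError("t must be >= 0")
    rate = life_table.annual_rate(attained_age)
    return 1.0 - math.exp(-rate * t)


@dataclass
class CycleProbabilities:
    """The five transition probabilities for one stage at one cycle."""

    prss: float   # remain stable
    pdss: float   # die from stable (natural mortality)
    ppss: float   # progress
    prps: float   # remain post-progression
    pdps: float   # die from post-progression

    def validate(self, tol: float = 1e-12) -> None:
        for name in ("prss", "pdss", "ppss", "prps", "pdps"):
            v = getattr(self, name)
            if not -tol <= v <= 1 + tol:
                raise DomainError(f"{name}={v} outside [0, 1]")
        if abs(self.prss + self.pdss + self.ppss - 1.0) > tol:
            raise DomainError("stable-state row does not sum to 1")
        if abs(self.prps + self.pdps - 1.0) > tol:
            raise DomainError("post-progression row does not sum to 1")


def cycle_probabilities(stage: StageParameters, attained_age: float,
                        settings: EconomicSettings,
                        life_table: LifeTable) -> CycleProbabilities:
    """Per-cycle transition probabilities at the given attained age."""
    t = settings.cycle_years
    pdss = natural_death_prob(attained_age, life_table, t)
    ppss = prob_progress(stage.median_pfs, t)
    if pdss + ppss > 1.0:
        log.warning("degenerate parameters at stage %s, age %.1f: "
                    "pdss+ppss=%.4f clamped", stage.stage_label, attained_age,
                    pdss + ppss)
        ppss = 1.0 - pdss
    prss = 1.0 - pdss - ppss
    pdps = prob_death_postprog(stage.median_os, stage.median_pfs, t, pdss)
    prps = 1.0 - pdps
    return CycleProbabilities(prss=prss, pdss=pdss, ppss=ppss,
                              prps=prps, pdps=pdps)


# ---------------------------------------------------------------------------
# cohort trace
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Expected per-cycle occupancy of one diagnosis-year cohort of one stage.

    Arrays have length ``n_cycles + 1``; index 0 is the entry cycle (everyone
    stable).  ``new_progressions[c]`` / ``new_deaths[c]`` are the expected
    event counts arriving at cycle *c* (fractions of the cohort, scaled by
    ``size``).  ``prps`` holds the per-transition stay probability of the
    post-progression state (entry j -> j+1), used downstream to follow
    sub-cohorts from their progression cycle.
    """

    stage_label: str
    entry_year: int
    size: float
    attained_age: np.ndarray
    frac_stable: np.ndarray
    frac_postprog: np.ndarray
    frac_dead: np.ndarray
    new_progressions: np.ndarray
    new_deaths: np.ndarray
    prps: np.ndarray = field(repr=False, default=None)

    @property
    def n_cycles(self) -> int:
        return self.frac_stable.size - 1

    def alive(self) -> np.ndarray:
        return self.frac_stable + self.frac_postprog

    def validate(self, tol: float = 1e-9) -> None:
        total = self.frac_stable + self.frac_postprog + self.frac_dead
        if np.max(np.abs(total - 1.0)) > tol:
            raise DomainError("state fractions do not sum to 1")
        if np.any(np.diff(self.frac_dead) < -tol):
            raise DomainError("frac_dead must be non-decreasing")
        if np.any(np.diff(self.frac_stable) > tol):
            raise DomainError("frac_stable must be non-increasing")
        if abs(self.frac_stable[0] - 1.0) > tol or self.frac_dead[0] > tol:
            raise DomainError("entry cycle must be fully stable")

    def postprogression_survival(self, c0: int) -> np.ndarray:
        """Survival of the sub-cohort that progressed at cycle *c0*.

        Element ``k`` is the probability of still being alive (in the
        post-progression state) at cycle ``c0 + k``; element 0 is 1.
        """
        stay = self.prps[c0:]
        out = np.empty(stay.size + 1)
        out[0] = 1.0
        np.cumprod(stay, out=out[1:])
        return out

    def to_frame(self) -> pd.DataFrame:
        n = self.frac_stable.size
        return pd.DataFrame({
            "stage": self.stage_label,
            "entry_year": self.entry_year,
            "cycle_index": np.arange(n),
            "attained_age": self.attained_age,
            "frac_stable": self.frac_stable,
            "frac_postprog": self.frac_postprog,
            "frac_dead": self.frac_dead,
            "new_progressions": self.new_progressions,
            "new_deaths": self.new_deaths,
        })


def run_cohort_trace(stage: StageParameters, entry_year: int, size: float,
                     settings: EconomicSettings, life_table: LifeTable,
                     n_cycles: int | None = None) -> CohortTrace:
    """Advance the expected occupancy of one cohort cycle by cycle.

    A cohort entering calendar year *k* is simulated until the end of the
    model horizon, i.e. for ``(last_year - k + 1)`` reporting years of
    ``cycles_per_year`` cycles each, unless *n_cycles* overrides it.
    """
    if size < 0:
        raise DomainError("size must be >= 0")
    if n_cycles is None:
        years = settings.last_year - entry_year + 1
        if years <= 0:
            raise DomainError("entry_year outside the model horizon")
        n_cycles = years * settings.cycles_per_year
    t = settings.cycle_years

    ages = stage.mean_age_dx + t * np.arange(n_cycles + 1)
    s = np.empty(n_cycles + 1)
    p = np.empty(n_cycles + 1)
    d = np.empty(n_cycles + 1)
    new_prog = np.zeros(n_cycles + 1)
    new_dead = np.zeros(n_cycles + 1)
    prps_arr = np.empty(n_cycles)
    s[0], p[0], d[0] = 1.0, 0.0, 0.0

    for c in range(n_cycles):
        probs = cycle_probabilities(stage, ages[c], settings, life_table)
        prps_arr[c] = probs.prps
        new_prog[c + 1] = s[c] * probs.ppss
        new_dead[c + 1] = s[c] * probs.pdss + p[c] * probs.pdps
        s[c + 1] = s[c] * probs.prss
        p[c + 1] = p[c] * probs.prps + new_prog[c + 1]
        d[c + 1] = d[c] + new_dead[c + 1]

    return CohortTrace(stage_label=stage.stage_label, entry_year=entry_year,
                       size=size, attained_age=ages, frac_stable=s,
                       frac_postprog=p, frac_dead=d,
                       new_progressions=new_prog, new_deaths=new_dead,
                       prps=prps_arr)


# ---------------------------------------------------------------------------
# incidence projection and multi-cohort run
# ---------------------------------------------------------------------------

def largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Integer apportionment of *total* by *shares* (largest remainder)."""
    shares = np.asarray(shares, dtype=float)
    shares = shares / shares.sum()
    quotas = shares * total
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:short]] += 1
    return counts


@dataclass
class IncidenceProjection:
    """Per-calendar-year incident counts, total and by stage."""

    years: np.ndarray
    oc_incidence: np.ndarray
    eoc_incidence: np.ndarray
    stage_counts: pd.DataFrame   # index year, columns stage labels

    def to_frame(self) -> pd.DataFrame:
        df = self.stage_counts.copy()
        df.insert(0, "eoc_incidence", self.eoc_incidence)
        df.insert(0, "oc_incidence", self.oc_incidence)
        return df


def project_incidence(settings: EconomicSettings,
                      spec: IncidenceSpec,
                      stages: dict) -> IncidenceProjection:
    """Linear incidence projection with a fixed stage distribution.

    Stage shares are taken from the stage parameters' incidence counts, so
    the first model year reproduces the published stage-level entries
    exactly under the default (largest-remainder) rounding.
    """
    spec.validate()
    years = np.arange(settings.first_year,
                      settings.first_year + settings.horizon_years)
    oc = spec.first_year_oc + spec.annual_increment * (years - years[0])
    if np.any(oc < 0):
        raise DomainError("incidence projection produced negative counts")
    eoc = spec.epithelial_fraction * oc

    shares = np.array([stages[s].incidence_count for s in STAGES], dtype=float)
    if shares.sum() <= 0:
        shares = np.array([stages[s].incidence_share for s in STAGES])
    shares = shares / shares.sum()

    rows = []
    eoc_out = np.empty_like(eoc)
    for i, total in enumerate(eoc):
        if spec.rounding == "largest_remainder":
            counts = largest_remainder(int(round(total)), shares)
        else:
            counts = shares * total
        eoc_out[i] = counts.sum()
        rows.append(counts)
    stage_counts = pd.DataFrame(rows, index=years, columns=list(STAGES))
    return IncidenceProjection(years=years, oc_incidence=oc,
                               eoc_incidence=eoc_out,
                               stage_counts=stage_counts)


def run_multi_cohort(params: ModelParameters) -> list[CohortTrace]:
    """One trace per (stage, entry year); later cohorts are shorter.

    Every cohort is truncated at the calendar end of the horizon, so a cohort
    entering in model year *k* (1-based) is simulated for
    ``horizon_years - k + 1`` years.
    """
    proj = project_incidence(params.economics, params.incidence, params.stages)
    traces = []
    for year in proj.years:
        for s in STAGES:
            size = float(proj.stage_counts.loc[year, s])
            traces.append(run_cohort_trace(params.stages[s], int(year), size,
                                           params.economics,
                                           params.life_table))
    return traces
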