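# Methods

## Model structure

The engine is a deterministic (expected-value) Markov cohort model with three
health states — *stable*, *post-progression*, *dead* — evaluated per FIGO
stage at diagnosis.  Stage is fixed at entry and never migrates.  Cycles are
21 days (one chemotherapy cycle); a reporting "year" is
`ceil(365.25/21) = 18` cycles (≈378 days), with the ~13-day residual absorbed
by the last bucket of each year.  Annual incident cohorts enter 2017–2026;
a cohort entering model year *k* is simulated for `11 − k` years, so every
trace truncates at the calendar end of the horizon.  There is no random
number generation anywhere in the engine: identical inputs produce
bit-identical traces, and the only seeded component is the synthetic-data
generator.

### Transition probabilities

Progression and post-progression death use exponential survival curves
parameterised by the stage's median PFS and median OS:
`Ppss(t) = 1 − exp(−t·ln2/me_PFS)` and
`Pdps(t) = 1 − exp(−t·ln2/(me_OS − me_PFS)) + Pnd`, capped at 1.
Death from the stable state is natural mortality only: the female life-table
rate at the floored attained age, converted by `1 − exp(−r·t)`.  Attained
age advances continuously (`age at diagnosis + cycle × 21/365.25`);
life-table and labour-schedule lookups clamp beyond the tabulated range.
If `Pnd + Ppss` ever exceeds one (degenerate inputs), the progression
probability is clamped and a warning logged.

No half-cycle correction is applied (a config switch exists but defaults to
off); state membership is evaluated at cycle start for costing.  Because the
discretisation is exact for exponentials, the cumulative progression in a
zero-mortality trace matches the closed-form CDF to < 1e-9 at every cycle
boundary — this is one of the test oracles.

### Incidence

A linear projector produces all-ovarian-cancer incidence per year
(default: 3,497 in the first year, zero increment — the published anchor
values of the underlying projection are not public, so growth is left
configurable).  The epithelial fraction (90 %) and a fixed stage split give
stage-level entries; the split is derived from the stage incidence counts
themselves so that, with largest-remainder rounding, the first model year
reproduces the published counts (1155/195/1116/681) exactly.  Fractional
(unrounded) counts are supported; costing is linear in cohort size, so the
choice only affects reporting granularity.

## Costing

All costs are in 2016 euros.  Historical unit costs are updated by compound
CPI (0.77 %/yr medicine CPI for healthcare items, 1.97 %/yr general CPI for
non-healthcare items; items marked `none` are already base-year tariffs).
Every stream is discounted at 3 %/yr at cycle resolution, measured from the
model start (2017) to the accrual cycle; cross-cohort offsets use whole
calendar years.

**Drug prices.** Public price = list price × (1 − statutory deduction) ×
(1 + 4 % VAT).  The statutory deduction rate is not published per drug; the
default is the general 7.5 % rate, applied only to catalogue entries flagged
as on-patent, and the sensitivity module sweeps it 0–6 %.  Doses follow the
catalogue rule: mg/m² via the Du Bois body-surface-area formula
(0.007184·h^0.725·w^0.425, stage-mean anthropometry), carboplatin via
Calvert (AUC × (GFR + 25), GFR a configurable constant of 100 mL/min since
no creatinine source is modelled), mg/kg (bevacizumab, 15 mg/kg default with
the 7.5 mg/kg label alternative as a scenario), or flat.  Intravenous drugs
are billed as whole vials with no sharing between patients; the solver finds
the cheapest covering vial combination by bounded exhaustive search and is
tested against brute-force enumeration.  Administration adds
€0.32/min × (infusion + 30 min preparation).  Expected per-cycle category
cost is the market-share-weighted mean over the category's components;
combination regimens are expressed through the shares.

**Treatment courses.** Neoadjuvant patients receive six cycles (three before
surgery, which is booked at cycle 3, and three after).  Adjuvant patients at
stages I–III receive a six-cycle adjuvant course.  Post-progression
chemotherapy at stages I–II is one six-cycle relapse line attached to each
progression sub-cohort.  The *advanced* category applies to post-progression
occupancy at stage III and to both states at stage IV; it is costed per
cycle of occupancy with **no duration cap by default** (`advanced_max_cycles:
null`), i.e. treatment continues while the patient occupies the treated
state.  This continuous-administration reading is the package's resolution
of an ambiguity in the source description, which names the states but not a
duration; the printed stage-IV chemotherapy magnitudes are consistent only
with continuous treatment, and a finite cap remains available in the config.
At stage IV, patients completing the neoadjuvant course continue on the
advanced regimen; the stable-state advanced uptake is the
surgery-plus-adjuvant mix share, and post-progression uptake is everyone
except the never-treated mix share.

**Other DHC.** The screening row covers the BRCA cascade patient side (20 %
tested × test + two counselling visits).  Relatives of the 5 % positive
(five each) accrue counselling plus six-monthly surveillance (transvaginal
ultrasound + CA125) for up to ten years, truncated at the horizon.  The
diagnostic workup (biopsy, biochemistry, vaginal ultrasound, CT, CA125) is a
one-off at entry.  Follow-up is a per-state annual schedule (defaults:
3 oncology visits + 3 CA125 + 1 ultrasound per stable year; 6 + 6 + 2 CT
post-progression — the underlying guideline frequencies are not published,
so the schedule ships as an editable default).  Hospitalisation and ER costs
apply the published semi-annual stage rates to all alive patients.  The
palliative pathway attaches to each death: 93.3 % outpatient follow-up
(nurse visits, package default 6.9 ≈ weekly over the 48-day window) vs 6.7 %
home team (9.5 home visits), four primary-care visits, a 59.6/40.4 %
home/hospital terminal-phase split, two nurse visits per day over the last
three days at home, and sedation drugs for 14 %.

**DNHC.** Formal care (public 9.5 % × 1.5 h/day, private 17.4 % × 8 h/day)
covers the last 48 days of life and attaches to deaths.  Informal care
(93.4 % × 10.3 h/day × €13.56/h) accrues by default over post-progression
occupancy: attaching it to a 48-day window is irreconcilable with the
magnitudes the published per-patient informal-care averages imply (a 48-day
episode is ≈ €6.7k per death, an order below the printed stage-III
per-patient-year figure), whereas post-progression accrual reproduces them
closely.  The window is a config option
(`last_48_days` / `post_progression` / `whole_disease`).

**IC (human-capital method).** Ages are cohort means, not distributions.
The initial temporary leave (expected 67 days: 30 % × 60 + 70 % × 70, with
"over 70" taken as exactly 70) books once per working-age diagnosed patient
at the employment rate and wage of the diagnosis age.  Progression before 65
starts a sick-leave stream until death or 65; person-time within one year of
progression books to temporary disability, beyond one year to permanent
disability.  Premature mortality sums employment-weighted wages from the
death age to 65.  Wages grow 1 %/yr and all IC streams are discounted at the
model rate (premature-mortality discounting has an off switch).  These rules
make all three IC rows exactly zero for stage IV (mean diagnosis age 68.1)
and permanent disability exactly zero for stage III (64.9 + progression
time ≥ 65 within a year) — matching the zeros in the published matrix, and
asserted as tests.

## Synthetic inputs

Four input tables are not published and are generated deterministically per
seed, clearly labelled as placeholders:

* **Unit costs** — realistic Spanish-magnitude medians per item with
  min/max columns emulating regional tariff spread (the min/max columns feed
  the test-and-visit price scenario), each with a source year and CPI
  category.
* **Drug catalogue** — the nine recommended drugs with label doses, plausible
  vial sizes/list prices (jittered per seed) and fixed market shares per
  category.
* **Life table** — Gompertz `r(age) = a·exp(b·age)` with a = 7e-6,
  b = 0.105 (≈ 4/1000 at 60, ≈ 5 % at 85, approximating contemporary
  Spanish female mortality).
* **Labour schedule** — ≈ 60 % employment through core working ages tapering
  to zero at 65, wages plateauing around €23k/yr.

What passing tests therefore show: the *mechanics* (traces, dose math,
aggregation, discounting, human-capital windows) are correct, and the
*qualitative* published pattern (steep stage gradient of per-patient cost,
DHC dominance, indirect costs concentrated at stage I and zero at stage IV,
informal care dominating DNHC) emerges from the structure under realistic
magnitudes.  What they do not show: agreement with the published absolute
euro totals, which depend on the real (unpublished) tariffs and prices.  The
published results matrix is shipped verbatim as a fixture and used only to
verify the aggregation layer (subtotals, shares, headline sums), never as a
model input.  One known discrepancy is documented there: the published
stage II share of the total is quoted as 3.9 % while the matrix cells give
116.6M/3102.3M = 3.76 %; the fixture reproduces the cell ratio.

## Sensitivity analysis

Ten deterministic one-way scenarios (see README) are applied as pure
perturbations of a deep-copied parameter registry — the base registry is
never mutated, asserted by bit-exact re-runs.  "Drug discount rate 0–6 %" is
interpreted as the statutory deduction rate (the config path can equally
sweep the model discount rate).  The genetic-counselling scenario endpoints
(35 %/70 %) sit above the 20 % base case; both are preserved as published.
Tornado rows are sorted by total-burden range width with alphabetical
tie-breaks.

## Numerical choices and limitations

* Expected-value cohort evaluation; no microsimulation, no probabilistic
  sensitivity analysis (the source analysis was deterministic).
* Cohorts carry mean ages, so IC eligibility is all-or-nothing per stage
  rather than an age distribution — this is what produces the exact zeros.
* Vial solver is exact (bounded branch-and-bound) for the small option sets
  that occur; no vial sharing, matching the source's conservative rule.
* Largest-remainder apportionment keeps integer stage counts summing to the
  rounded epithelial total.
* Stage III's published treatment mix sums to 99.9 % (printed rounding); it
  is kept verbatim and the mix-sum validation tolerance is 0.002.
* Problem sizes: 40 cohort traces of ≤ 180 cycles; a full run takes ~2 s and
  the ten-scenario tornado ~10 s on one CPU.
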