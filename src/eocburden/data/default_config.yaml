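# eocburden default configuration (version 0.1.0)
#
# Every key shown here equals the built-in default: running with this file is
# identical to running with no config at all.  Override any subset; unknown
# keys are rejected with an error naming the field.
#
# The four input tables that are not parameterised here (unit costs, drug
# catalogue, life table, labour schedule) are generated deterministically
# from `seed` by the synthetic-data module; point `unit_costs`,
# `catalogue`, `life_table` or `labour` at CSV files to replace them.

seed: 0

economics:
  discount_rate_annual: 0.03     # annual discount rate on all cost streams
  medicine_cpi: 0.0077           # CPI for updating healthcare unit costs
  general_cpi: 0.0197            # CPI for non-healthcare unit costs
  productivity_growth: 0.01      # annual growth of wages in productivity loss
  vat_drugs: 0.04                # VAT on medicines
  drug_deduction_rate: 0.075     # statutory deduction on on-patent products
  base_year: 2016                # all costs expressed in euros of this year
  first_year: 2017               # first incident cohort
  horizon_years: 10
  cycle_days: 21                 # one chemotherapy cycle
  retirement_age: 65
  admin_cost_per_min: 0.32       # day-hospital administration fee
  admin_prep_min: 30             # fixed preparation time per infusion

# stage-level epidemiology, survival medians and treatment mixes
stages:
  I:
    incidence_count: 1155
    incidence_share: 0.37
    median_pfs: 18.33            # years
    median_os: 19.50
    mean_age_dx: 57.4
    mean_weight: 65
    mean_height: 159
    hosp_per_6mo: 1.2
    pct_hospitalized: 0.154
    er_per_6mo: 1.5
    pct_er: 0.231
    treatment_mix: {none: 0.0, surgery_only: 0.667,
                    neoadjuvant_plus_surgery: 0.0,
                    surgery_plus_adjuvant: 0.333}
    surgery_mix: {laparotomy: 1.0, omentectomy: 0.0, hysterectomy: 1.0,
                  salpingo_oophorectomy: 0.0, lymphadenectomy: 0.0}
  II:
    incidence_count: 195
    incidence_share: 0.06
    median_pfs: 6.25
    median_os: 7.50
    mean_age_dx: 62.4
    mean_weight: 67
    mean_height: 160
    hosp_per_6mo: 1.2
    pct_hospitalized: 0.154
    er_per_6mo: 1.5
    pct_er: 0.231
    treatment_mix: {none: 0.0, surgery_only: 0.198,
                    neoadjuvant_plus_surgery: 0.0,
                    surgery_plus_adjuvant: 0.802}
    surgery_mix: {laparotomy: 1.0, omentectomy: 0.0638, hysterectomy: 1.0,
                  salpingo_oophorectomy: 1.0, lymphadenectomy: 0.0}
  III:
    incidence_count: 1116
    incidence_share: 0.35
    median_pfs: 2.00
    median_os: 3.20
    mean_age_dx: 64.9
    mean_weight: 65
    mean_height: 159
    hosp_per_6mo: 2.1
    pct_hospitalized: 0.482
    er_per_6mo: 1.7
    pct_er: 0.222
    treatment_mix: {none: 0.031, surgery_only: 0.113,
                    neoadjuvant_plus_surgery: 0.144,
                    surgery_plus_adjuvant: 0.711}
    surgery_mix: {laparotomy: 1.0, omentectomy: 1.0, hysterectomy: 1.0,
                  salpingo_oophorectomy: 1.0, lymphadenectomy: 0.75}
  IV:
    incidence_count: 681
    incidence_share: 0.22
    median_pfs: 1.60
    median_os: 1.90
    mean_age_dx: 68.1
    mean_weight: 66
    mean_height: 160
    hosp_per_6mo: 2.1
    pct_hospitalized: 0.482
    er_per_6mo: 1.7
    pct_er: 0.222
    treatment_mix: {none: 0.088, surgery_only: 0.088,
                    neoadjuvant_plus_surgery: 0.242,
                    surgery_plus_adjuvant: 0.582}
    surgery_mix: {laparotomy: 1.0, omentectomy: 1.0, hysterectomy: 1.0,
                  salpingo_oophorectomy: 1.0, lymphadenectomy: 1.0}

incidence:
  first_year_oc: 3497            # all ovarian cancers, first model year
  annual_increment: 0            # linear yearly change
  epithelial_fraction: 0.90
  rounding: largest_remainder    # or "fractional"

care:
  pct_private: 0.174
  pct_public: 0.095
  pct_informal: 0.934
  hours_public: 1.5              # caregiver hours per day
  hours_private: 8.0
  hours_informal: 10.3
  wage_per_hour: 13.56           # proxy-good caregiver valuation
  formal_care_days: 48

cascade:
  pct_tested: 0.20               # patients referred to BRCA1/2 testing
  counselling_visits: 2
  pct_positive: 0.05
  relatives_per_positive: 5

palliative:
  duration_days: 48
  pct_outpatient: 0.933
  pct_home_team: 0.067
  home_visits: 9.5
  outpatient_nurse_visits: 6.9
  primary_care_visits: 4
  pct_terminal_home: 0.596
  pct_terminal_hospital: 0.404
  terminal_home_days: 3
  nurse_visits_per_day: 2
  pct_sedation: 0.14

chemo:
  gfr_ml_min: 100                # glomerular filtration rate for Calvert
  bevacizumab_dose_per_kg: 15.0
  neoadjuvant_cycles: 6          # 3 pre-operative + 3 post-operative
  adjuvant_cycles: 6
  post_progression_max_cycles: 6 # one relapse line at early stages
  advanced_max_cycles: null      # null = while occupying the treated state

followup:                        # annual frequencies per alive patient
  stable: {oncology_visit: 3.0, ca125: 3.0, tvus: 1.0}
  post_progression: {oncology_visit: 6.0, ca125: 6.0, ct_scan: 2.0}

surveillance_years: 10           # relatives' six-monthly surveillance window
test_visit_cost_column: unit_cost      # unit_cost_min / unit_cost / unit_cost_max
informal_care_window: post_progression # last_48_days / post_progression / whole_disease
premature_mortality_discounted: true
half_cycle_correction: false
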