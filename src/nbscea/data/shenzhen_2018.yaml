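# Baseline parameter set for the Shenzhen 2018 expanded newborn-screening
# evaluation. All monetary values in 2018 RMB. Incidences are the printed
# decimal values of the source incidence table (not re-derived from the
# 1:N ratios), so downstream results match that table's rounding.
name: shenzhen_2018
courses: packaged

assays:
  IF:
    sensitivity: 1.00
    specificity: 0.786
    screen_cost: 23.0
    confirm_cost: 319.0
    followup_cost: 1276.0   # 4 visits per year
  MSMS:
    sensitivity: 1.00
    specificity: 1.00
    screen_cost: 296.0
    confirm_cost: 296.0
    followup_cost: 1184.0   # 4 visits per year

diseases:
  - code: PKU           # 1:14,028, field investigation
    incidence: 0.00007128
    sequelae: [ND]
    treatment_cost_0_5: 15000.00
    treatment_cost_6_82: 15000.00
  - code: MSUD          # 1:206,667
    incidence: 0.00000484
    sequelae: [ND, DD]
    treatment_cost_0_5: 13440.90
    treatment_cost_6_82: 6083.00
  - code: CIT1          # 1:265,700
    incidence: 0.00000376
    sequelae: [MR]
    treatment_cost_0_5: 48202.46
    treatment_cost_6_82: 20833.77
  - code: CIT2          # no published incidence row; assumed equal to CIT1
    incidence: 0.00000376
    incidence_assumed: true
    sequelae: [MR]
    treatment_cost_0_5: 48202.46
    treatment_cost_6_82: 20833.77
  - code: HCY           # 1:212,622
    incidence: 0.0000047
    sequelae: [MR]
    treatment_cost_0_5: 13772.13
    treatment_cost_6_82: 5952.51
  - code: MMA           # 1:46,500
    incidence: 0.00002151
    sequelae: [ND, RD]
    treatment_cost_0_5: 19023.76
    treatment_cost_6_82: 24692.53
  - code: IVA           # 1:265,900
    incidence: 0.00000376
    sequelae: [ND, RD]
    treatment_cost_0_5: 17567.81
    treatment_cost_6_82: 13045.01
  - code: GA1           # 1:310,200
    incidence: 0.00000322
    sequelae: [ND]
    treatment_cost_0_5: 17567.81
    treatment_cost_6_82: 13045.01
  - code: PA            # 1:310,200
    incidence: 0.00000322
    sequelae: [ND, RD]
    treatment_cost_0_5: 17567.81
    treatment_cost_6_82: 19839.39
  - code: PCD           # 1:23,862
    incidence: 0.00004191
    sequelae: [DD]
    treatment_cost_0_5: 15853.26
    treatment_cost_6_82: 15853.26
  - code: MCAD          # 1:372,252
    incidence: 0.00000269
    sequelae: [DD]
    treatment_cost_0_5: 15853.26
    treatment_cost_6_82: 15853.26
  - code: VLCAD         # 1:620,421
    incidence: 0.000001611
    sequelae: [DD]
    treatment_cost_0_5: 15853.26
    treatment_cost_6_82: 15853.26

utilities:
  values:
    NS: 0.900      # diseased, no sequela
    DD: 0.843      # development delay
    ND: 0.840      # neurological damage
    MR: 0.790      # mental retardation
    RD: 0.670      # renal damage
    Alive: 1.0     # healthy (research assumption)
    Dead: 0.0
  bounds:
    NS: [0.850, 0.950]
    DD: [0.792, 0.881]
    ND: [0.700, 0.850]
    MR: [0.590, 0.840]
    RD: [0.580, 0.740]

costs:
  sequela_care:          # treatment for sequelae, per person-year
    DD: 3064.0
    ND: 53400.0
    MR: 12000.0
    RD: 70213.0
  transport: 435.0           # per year, during confirmation/treatment/follow-up
  lost_productivity: 3060.0  # per year, family time lost
  program_fixed:             # per year, whole program
    sample_transport: 42000.0
    printing: 340000.0
    cold_chain: 470000.0
    software_equipment: 370000.0
  program_per_person:        # per screened person-year
    utilities: 2.52
    admin: 1.81

econ:
  discount_rate: 0.03
  cohort_size: 200000
  horizon: 82
  cycle_length: 1.0
  per_capita_gdp: 189568.0
  icer_threshold: 568704.0   # 3 x per-capita GDP
  gov_share_screening: 0.80
  gov_share_treatment: 0.60
  bia_years: 10
  discount_timing: mid
  unscreened_cost_onset: sequela
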