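# US payer perspective, base case.
# Costs are USD per 3-week treatment cycle (drugs, imaging, BSC) or per event
# (adverse-event management).  Ranges are the published intervals where one
# was printed; parameters without an entry under `ranges` default to +/-30%.
# Survival inputs are pinned to the trial's median PFS/OS with a mild
# wear-out shape (gamma = 1.1); the trial's fitted parameters were never
# published, so these are calibrated stand-ins.
country: USA
wtp: 150000.0
discount_rate: 0.03
cycle_length_days: 21
horizon_years: 10
start_age: 55

drug_cost_per_cycle:
  tucatinib: 12950.0
  trastuzumab: 3669.08
  capecitabine: 955.50

arm_drugs:
  TXT: [tucatinib, trastuzumab, capecitabine]
  TX: [trastuzumab, capecitabine]

imaging_cost_per_cycle: 448.0
bsc_cost_per_cycle: 2933.0

ae_unit_cost:
  palmar_plantar_erythrodysesthesia: 8.31
  diarrhea: 1183.70
  alt_ast_increased: 76.0
  fatigue: 6908.0
  anemia: 13679.0
  nausea_vomiting: 5246.0
  stomatitis: 10073.67
  neutropenia: 9910.0

# grade 3-4 incidences per arm (trial-level assumptions; see docs/methods.md)
ae_incidence:
  TXT:
    palmar_plantar_erythrodysesthesia: 0.131
    diarrhea: 0.129
    alt_ast_increased: 0.080
    fatigue: 0.047
    anemia: 0.025
    nausea_vomiting: 0.020
    stomatitis: 0.010
    neutropenia: 0.005
  TX:
    palmar_plantar_erythrodysesthesia: 0.091
    diarrhea: 0.086
    alt_ast_increased: 0.025
    fatigue: 0.041
    anemia: 0.020
    nausea_vomiting: 0.015
    stomatitis: 0.005
    neutropenia: 0.005

utility_pfs: 0.86
utility_pd: 0.71

survival:
  TXT:
    pfs: {median_months: 7.8, shape_gamma: 1.1}
    os: {median_months: 21.9, shape_gamma: 1.1}
  TX:
    pfs: {median_months: 5.6, shape_gamma: 1.1}
    os: {median_months: 17.4, shape_gamma: 1.1}

subgroups:
  brain_metastases:
    survival:
      TXT:
        pfs: {median_months: 7.6, shape_gamma: 1.1}
        os: {median_months: 18.1, shape_gamma: 1.1}
      TX:
        pfs: {median_months: 5.4, shape_gamma: 1.1}
        os: {median_months: 12.0, shape_gamma: 1.1}

life_table:
  fixture: {age_start: 18, age_end: 100, q0: 0.0003, doubling_years: 8}

ranges:
  cost.drug.tucatinib: [9065.0, 16835.0]
  cost.drug.trastuzumab: [2568.36, 4769.80]
  cost.drug.capecitabine: [668.85, 1242.15]
  cost.bsc: [2053.1, 3812.9]
  cost.imaging: [313.6, 582.4]
  cost.ae.palmar_plantar_erythrodysesthesia: [5.82, 10.80]
  cost.ae.diarrhea: [828.59, 1538.81]
  cost.ae.anemia: [9575.0, 17783.0]
  cost.ae.stomatitis: [7051.57, 13095.77]
  cost.ae.neutropenia: [6937.0, 12883.0]
  utility.pfs: [0.602, 1.0]
  utility.pd: [0.497, 0.923]

psa_fixed: [trastuzumab, capecitabine]
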