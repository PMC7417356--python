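# Chinese payer perspective, base case.  Costs already expressed in USD at
# the Feb-2020 rate of 6.9851 CNY per USD; the triplet's add-on drug is
# priced at the local comparator TKI since it is not yet marketed.
# See usa_base.yaml for conventions.
country: China
wtp: 30447.09
discount_rate: 0.03
cycle_length_days: 21
horizon_years: 10
start_age: 55

drug_cost_per_cycle:
  tucatinib: 1002.03
  trastuzumab: 952.01
  capecitabine: 189.60

arm_drugs:
  TXT: [tucatinib, trastuzumab, capecitabine]
  TX: [trastuzumab, capecitabine]

imaging_cost_per_cycle: 84.56
bsc_cost_per_cycle: 807.0

ae_unit_cost:
  palmar_plantar_erythrodysesthesia: 3.57
  diarrhea: 12.79
  alt_ast_increased: 24.15
  fatigue: 103.00
  anemia: 921.10
  nausea_vomiting: 39.60
  stomatitis: 42.20
  neutropenia: 411.93

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
  cost.drug.tucatinib: [701.42, 1302.64]
  cost.drug.trastuzumab: [666.41, 1237.61]
  cost.drug.capecitabine: [132.72, 246.48]
  cost.bsc: [564.9, 1049.1]
  cost.imaging: [59.19, 109.9]
  cost.ae.palmar_plantar_erythrodysesthesia: [2.50, 4.64]
  cost.ae.diarrhea: [8.95, 16.63]
  cost.ae.alt_ast_increased: [16.90, 31.40]
  cost.ae.fatigue: [72.10, 133.90]
  cost.ae.anemia: [348.60, 1494.32]
  cost.ae.nausea_vomiting: [27.72, 51.48]
  cost.ae.stomatitis: [29.54, 54.86]
  cost.ae.neutropenia: [288.35, 535.51]
  utility.pfs: [0.602, 1.0]
  utility.pd: [0.497, 0.923]

psa_fixed: [trastuzumab, capecitabine]
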