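# Subgroup scenario: mismatch-repair-proficient (pMMR) population.
# Transition probabilities and survival medians differ from the base
# case; all costs and utilities are shared with it.
#
# The LP "drug_acquisition_monthly_total" exceeds the sum of its drug
# components by 4 x the per-10-minute administration cost (a 40
# minutes-per-month infusion component); the chemotherapy total likewise
# carries an administration/residual component not broken out in the
# source table and is used as published.
label: KEYNOTE-775 pMMR subgroup
population: pMMR
horizon_cycles: 600
cycle_length_months: 1.0
discount_annual_rate: 0.03
wtp_per_qaly: 100000.0
half_cycle_correction: true
administration_cost_per_10min:
  base: 55.98
  low: 41.99
  high: 69.98
  distribution: Gamma
utilities:
  pfs: {base: 0.817, low: 0.613, high: 1.000, distribution: Beta}
  pd: {base: 0.779, low: 0.584, high: 0.974, distribution: Beta}
  death: 0.0
shared_costs:
  disease_management_monthly:
    {base: 360.42, low: 270.32, high: 450.53, distribution: Gamma}
  dmmr_msih_testing_entry:
    {base: 666.40, low: 499.80, high: 833.00, distribution: Gamma}
  palliative_care_on_death:
    {base: 11266.07, low: 8449.55, high: 14082.59, distribution: Gamma}
arms:
  - name: LP
    role: intervention
    transitions:
      pfs_pfs: 0.895
      pfs_pd: 0.066
      pfs_death: 0.039
      pd_pd: 0.937
      pd_death: 0.063
    drug_acquisition_monthly_total: 32820.76
    administration_minutes_monthly: 40.0
    drugs:
      - name: Lenvatinib
        monthly_cost: 16166.98
        low: 12125.24
        high: 20208.73
        distribution: Gamma
      - name: Pembrolizumab
        monthly_cost: 16429.87
        low: 12322.40
        high: 20537.34
        distribution: Gamma
    adverse_events:
      - name: Hypertension
        grade34_rate: 0.379
        management_cost: 7965.60
        low: 5974.20
        high: 9957.00
        distribution: Gamma
      - name: Diarrhea
        grade34_rate: 0.076
        management_cost: 7795.80
        low: 5846.85
        high: 9744.75
        distribution: Gamma
    subsequent_therapy_acceptance_rate: 0.280
  - name: Chemotherapy
    role: comparator
    transitions:
      pfs_pfs: 0.809
      pfs_pd: 0.135
      pfs_death: 0.056
      pd_pd: 0.904
      pd_death: 0.096
    drug_acquisition_monthly_total: 765.31
    drugs:
      - name: Doxorubicin
        monthly_cost: 164.16
        low: 123.12
        high: 205.20
        distribution: Gamma
      - name: Paclitaxel
        monthly_cost: 205.20
        low: 153.90
        high: 256.50
        distribution: Gamma
    adverse_events:
      - name: Anemia
        grade34_rate: 0.147
        management_cost: 14314.20
        low: 10735.65
        high: 17892.75
        distribution: Gamma
      - name: Neutropenia
        grade34_rate: 0.258
        management_cost: 14429.73
        low: 10822.30
        high: 18037.16
        distribution: Gamma
      - name: Neutrophil count decreased
        grade34_rate: 0.212
        management_cost: 14429.73
        low: 10822.30
        high: 18037.16
        distribution: Gamma
      - name: WBC decreased
        grade34_rate: 0.103
        management_cost: 7071.65
        low: 5303.74
        high: 8839.56
        distribution: Gamma
    subsequent_therapy_acceptance_rate: 0.481
survival:
  LP: {median_pfs_months: 6.6, median_os_months: 17.4}
  Chemotherapy: {median_pfs_months: 3.8, median_os_months: 12.0}
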