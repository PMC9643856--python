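# Base-case model configuration: all unit prices in 2021 USD, survival
# scales per month, ranges are the published sensitivity-analysis bounds.
settings:
  cycle_length_days: 21
  n_cycles: 120
  annual_discount_rate: {base: 0.05, low: 0.0, high: 0.08, distribution: fixed}
  wtp_threshold: 37653
  engine_mode: state_transition
  half_cycle_correction: false

patient:
  weight_kg: 65
  height_m: 1.64
  bsa_m2: {base: 1.72, low: 1.38, high: 2.06, distribution: normal}
  crcl_ml_min: {base: 70.0, low: 52.5, high: 87.5, distribution: gamma}

survival:
  adchm:
    pfs:
      scale: {base: 0.1489507, low: 0.119161, high: 0.178741, distribution: survival_param}
      shape: {base: 2.070122, low: 1.656098, high: 2.484146, distribution: survival_param}
    os:
      scale: {base: 0.06284631, low: 0.050277, high: 0.075416, distribution: survival_param}
      shape: {base: 1.924522, low: 1.539618, high: 2.309426, distribution: survival_param}
  plchm:
    pfs:
      scale: {base: 0.1767604, low: 0.141408, high: 0.212112, distribution: survival_param}
      shape: {base: 3.377706, low: 2.702165, high: 4.053247, distribution: survival_param}
    os:
      scale: {base: 0.07650712, low: 0.061206, high: 0.091809, distribution: survival_param}
      shape: {base: 2.665497, low: 2.132398, high: 3.198596, distribution: survival_param}

drugs:
  adebrelimab:  {vial_mg: 100, price: {base: 25.77, low: 20.62, high: 30.92, distribution: gamma}}
  carboplatin:  {vial_mg: 100, price: {base: 4.10,  low: 3.28,  high: 4.92,  distribution: gamma}}
  etoposide:    {vial_mg: 100, price: {base: 1.21,  low: 0.97,  high: 1.45,  distribution: gamma}}
  irinotecan:   {vial_mg: 100, price: {base: 274.90, low: 219.92, high: 329.88, distribution: gamma}}
  cisplatin:    {vial_mg: 100, price: {base: 11.74, low: 9.39,  high: 14.09, distribution: gamma}}

regimen:
  chemo_max_cycles: 6
  carboplatin_auc: 5.0
  etoposide_mg_per_m2: 100.0
  etoposide_days_per_cycle: 3
  adebrelimab_mg_per_kg: 20.0
  maintenance_cap_months: 24.0
  second_line:
    irinotecan_mg_per_m2: 65.0
    irinotecan_days_per_cycle: 2
    cisplatin_mg_per_m2: 75.0
    cisplatin_days_per_cycle: 1
    duration_cycles: 3.6

costs:
  followup_per_cycle: {base: 73.86,  low: 59.09,  high: 88.64,  distribution: gamma}
  tests_per_cycle:    {base: 152.09, low: 121.67, high: 182.51, distribution: gamma}
  bsc_per_cycle:      {base: 359.00, low: 287.20, high: 430.80, distribution: gamma}
  end_of_life:        {base: 2176.00, low: 1740.80, high: 2611.20, distribution: gamma}
  pd_followup: true
  pd_tests: true

utilities:
  pfs: {base: 0.673, low: 0.538, high: 0.808, distribution: beta}
  pd:  {base: 0.473, low: 0.378, high: 0.568, distribution: beta}

# grade >=3 adverse events with incidence > 5%; disutilities are one-off
adverse_events:
  adchm:
    - name: neutropenia
      incidence:  {base: 0.757, low: 0.606, high: 0.908, distribution: beta}
      cost:       {base: 84.21, low: 67.37, high: 101.05, distribution: gamma}
      disutility: {base: 0.20,  low: 0.16,  high: 0.24,  distribution: beta}
    - name: leukopenia
      incidence:  {base: 0.461, low: 0.369, high: 0.553, distribution: beta}
      cost:       {base: 466.00, low: 372.80, high: 559.20, distribution: gamma}
      disutility: {base: 0.20,  low: 0.16,  high: 0.24,  distribution: beta}
    - name: thrombocytopenia
      incidence:  {base: 0.383, low: 0.306, high: 0.460, distribution: beta}
      cost:       {base: 1054.00, low: 843.20, high: 1264.80, distribution: gamma}
      disutility: {base: 0.19,  low: 0.15,  high: 0.23,  distribution: beta}
    - name: anemia
      incidence:  {base: 0.278, low: 0.222, high: 0.334, distribution: beta}
      cost:       {base: 508.20, low: 406.56, high: 609.84, distribution: gamma}
      disutility: {base: 0.073, low: 0.058, high: 0.088, distribution: beta}
  plchm:
    - name: neutropenia
      incidence:  {base: 0.754, low: 0.603, high: 0.905, distribution: beta}
      cost:       {base: 84.21, low: 67.37, high: 101.05, distribution: gamma}
      disutility: {base: 0.20,  low: 0.16,  high: 0.24,  distribution: beta}
    - name: leukopenia
      incidence:  {base: 0.379, low: 0.303, high: 0.455, distribution: beta}
      cost:       {base: 466.00, low: 372.80, high: 559.20, distribution: gamma}
      disutility: {base: 0.20,  low: 0.16,  high: 0.24,  distribution: beta}
    - name: thrombocytopenia
      incidence:  {base: 0.336, low: 0.269, high: 0.403, distribution: beta}
      cost:       {base: 1054.00, low: 843.20, high: 1264.80, distribution: gamma}
      disutility: {base: 0.19,  low: 0.15,  high: 0.23,  distribution: beta}
    - name: anemia
      incidence:  {base: 0.284, low: 0.227, high: 0.341, distribution: beta}
      cost:       {base: 508.20, low: 406.56, high: 609.84, distribution: gamma}
      disutility: {base: 0.073, low: 0.058, high: 0.088, distribution: beta}

# post-progression mix: chemo fraction gets second-line, remainder BSC
proportions:
  second_line_chemo:
    adchm: {base: 0.40, low: 0.32, high: 0.48, distribution: beta}
    plchm: {base: 0.52, low: 0.42, high: 0.62, distribution: beta}
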