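# Analytical Eco-scale penalty-point rule tables.
# Reagent penalty = pictogram_count * signal_word_multiplier * amount_multiplier.
# Instrument, occupational-hazard and waste penalties are direct bracket lookups.
signal_word:
  none: 0
  warning: 1
  danger: 2
reagent_amount:          # per-sample solvent/reagent consumption
  "<10 mL": 1
  "10-100 mL": 2
  ">100 mL": 3
instrument_energy:       # kWh per sample
  "<=0.1 kWh": 0
  "<=1.5 kWh": 1
  ">1.5 kWh": 2
occupational_hazard:
  hermetic: 0
  vapour emission: 3
waste:
  none: 0
  "<1 mL": 1
  "1-10 mL": 3
  ">10 mL": 5
verdict_thresholds:      # score strictly greater than the bound
  excellent: 75
  acceptable: 50
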