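# Default per-BQE record-selection criteria.
# Acute window: 0-5 days = 0-120 hours = 0-7200 minutes.
# Edit a copy and pass it via --criteria / default_criteria(config_path=...).
Algae:
  dosing_group: water_concentration
  day_units: [d, dph, dpf]
  hour_units: [h, ht, hph, hpf, hv]
  minute_units: [mi]
  min_d: 0.0
  max_d: 5.0
  min_h: 0.0
  max_h: 120.0
  min_m: 0.0
  max_m: 7200.0
  habitat: Water
  species_selection: all
  effects: [MOR, GRO, POP, REP, MPH, DEV]
  quantile: 0.05
Crustacean:
  dosing_group: water_concentration
  day_units: [d, dph, dpf]
  hour_units: [h, ht, hph, hpf, hv]
  minute_units: [mi]
  min_d: 0.0
  max_d: 5.0
  min_h: 0.0
  max_h: 120.0
  min_m: 0.0
  max_m: 7200.0
  habitat: Water
  species_selection: standard_test_species
  effects: [MOR, GRO, POP, REP, MPH, DEV, ITX]
  quantile: 0.05
Fish:
  dosing_group: water_concentration
  day_units: [d, dph, dpf]
  hour_units: [h, ht, hph, hpf, hv]
  minute_units: [mi]
  min_d: 0.0
  max_d: 5.0
  min_h: 0.0
  max_h: 120.0
  min_m: 0.0
  max_m: 7200.0
  habitat: Water
  species_selection: standard_test_species
  effects: [MOR, GRO, POP, REP, MPH, DEV]
  quantile: 0.05
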