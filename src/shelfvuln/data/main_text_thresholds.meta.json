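{
 "units": {
  "oxygen": "mg/L",
  "temperature": "degC",
  "salinity": "practical salinity",
  "depth": "m",
  "ph": "pH units"
 },
 "columns": [
  "latin_name",
  "common_name",
  "life_stage",
  "habitat_zone",
  "source_id",
  "criteria",
  "provenance",
  "oxygen_preferred_min",
  "oxygen_preferred_max",
  "oxygen_critical_min",
  "oxygen_critical_max",
  "oxygen_lc50_min",
  "oxygen_lc50_max",
  "oxygen_no_survival_min",
  "oxygen_no_survival_max",
  "temperature_range_min",
  "temperature_range_max",
  "temperature_preferred_min",
  "temperature_preferred_max",
  "temperature_intolerant_low",
  "temperature_intolerant_high",
  "temperature_lethal_low",
  "temperature_lethal_high",
  "salinity_range_min",
  "salinity_range_max",
  "salinity_preferred_min",
  "salinity_preferred_max",
  "salinity_intolerant_low",
  "salinity_intolerant_high",
  "salinity_lethal_low",
  "salinity_lethal_high",
  "depth_range_min",
  "depth_range_max",
  "depth_mean",
  "depth_preferred_min",
  "depth_preferred_max",
  "ph_level",
  "ph_response_code",
  "ph_response_variable",
  "ph_evidence"
 ],
 "aggregates": {
  "demersal_lc50_span_mg_per_L": [
   0.9,
   2.4
  ]
 },
 "notes": {
  "Gadus morhua lc50_max": "inferred: upper end of the demersal median-lethal span (0.9-2.4 mg/L); the species-specific value is supplement-only and not packaged",
  "scope": "subset of main-text printed thresholds; the full 54-species compilation is deliberately not reproduced"
 }
}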