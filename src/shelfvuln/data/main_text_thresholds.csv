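latin_name,common_name,life_stage,habitat_zone,source_id,criteria,provenance,oxygen_preferred_min,oxygen_preferred_max,oxygen_critical_min,oxygen_critical_max,oxygen_lc50_min,oxygen_lc50_max,oxygen_no_survival_min,oxygen_no_survival_max,temperature_range_min,temperature_range_max,temperature_preferred_min,temperature_preferred_max,temperature_intolerant_low,temperature_intolerant_high,temperature_lethal_low,temperature_lethal_high,salinity_range_min,salinity_range_max,salinity_preferred_min,salinity_preferred_max,salinity_intolerant_low,salinity_intolerant_high,salinity_lethal_low,salinity_lethal_high,depth_range_min,depth_range_max,depth_mean,depth_preferred_min,depth_preferred_max,ph_level,ph_response_code,ph_response_variable,ph_evidence
Anarhichas lupus,Atlantic wolffish,adult,demersal,pers-comm,SC,,,,5.69,6.64,,,,,,,,,,,,,,,,,,,,,,,,,,,,,
Anarhichas lupus,Atlantic wolffish,adult,demersal,OH02,SC,,,,,,,,,,,10.0,,,,,,,,,,,,,,,,,,,,,,,
Anarhichas lupus,Atlantic wolffish,adult,demersal,S82,SC,,,,,,,,,,,13.0,,,,,,,,,,,,,,,,,,,,,,,
Gadus morhua,Atlantic cod,adult,demersal,lit-cod-o2,CF;E,,,,2.9,3.19,,,,,,,,,,,,,,,,,,,,,,,,,,,,,
Gadus morhua,Atlantic cod,adult,demersal,demersal-span,CF;E,inferred,,,,,,2.4,,,,,,,,,,,,,,,,,,,,,,,,,,,
Gadus morhua,Atlantic cod,adult,demersal,L04,CF;E,,,,,,,,,,,,,10.0,,,,,,,,,,,,,,,,,,,,,
Salmo salar,Atlantic salmon,adult,pelagic,lit-salmon-o2,SC,,,,4.0,5.0,,,,,,,,,,,,,,,,,,,,,,,,,,,,,
Salmo salar,Atlantic salmon,post-smolt,pelagic,lit-salmon-ps,SC,,,,4.82,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,
Glyptocephalus cynoglossus,Witch flounder,unspecified,demersal,lit-witch-o2,CF,,,,,,,,0.97,2.15,,,,,,,,,,,,,,,,,,,,,,,,,
Chionoecetes opilio,Snow crab,unspecified,benthic,lit-crab-t,CF,,,,,,,,,,-1.0,4.0,,,,,,,,,,,,,,,,,,,,,,,
Streblospio benedicti,Spionid polychaete,unspecified,infaunal,lit-spionid-o2,EET,,,,0.57,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,
Crassostrea virginica,American oyster,unspecified,benthic,lit-oyster-o2,CF,,,,,,0.0,,,,,,,,,,,,,,,,,,,,,,,,,,,,
Callinectes sapidus,Blue crab,juvenile,benthic,lit-bluecrab-o2,VS,,,,,,4.08,6.44,,,,,,,,,,,,,,,,,,,,,,,,,,,
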