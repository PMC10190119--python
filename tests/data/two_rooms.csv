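building_id,room_id,date,observer_id,floor_level,room_type,odor_intensity,odor_score,odor_source,odor_source_unknown,ceiling_present,ceiling_damage_stain,ceiling_visible_mold,ceiling_wet_damp,ceiling_near_exterior,ceiling_nothing_found,ceiling_note,walls_present,walls_damage_stain,walls_visible_mold,walls_wet_damp,walls_near_exterior,walls_nothing_found,walls_note,floor_present,floor_damage_stain,floor_visible_mold,floor_wet_damp,floor_near_exterior,floor_nothing_found,floor_note,windows_present,windows_damage_stain,windows_visible_mold,windows_wet_damp,windows_near_exterior,windows_nothing_found,windows_note,furnishings_present,furnishings_damage_stain,furnishings_visible_mold,furnishings_wet_damp,furnishings_near_exterior,furnishings_nothing_found,furnishings_note,hvac_present,hvac_damage_stain,hvac_visible_mold,hvac_wet_damp,hvac_near_exterior,hvac_nothing_found,hvac_note,supplies_materials_present,supplies_materials_damage_stain,supplies_materials_visible_mold,supplies_materials_wet_damp,supplies_materials_near_exterior,supplies_materials_nothing_found,supplies_materials_note,pipes_present,pipes_damage_stain,pipes_visible_mold,pipes_wet_damp,pipes_near_exterior,pipes_nothing_found,pipes_note,assessment_notes,schema_version
B01,R101,2024-05-01,OBS1,1,classroom,mild,1,,1,1,2,0,0,1,0,acoustic tile,1,1,1,0,0,0,,1,0,0,0,0,1,,1,0,0,1,0,0,condensation on sill,,,,,,,,,,,,,,,,,,,,,,,,,,,,,stain under roof joint,dmat-csv-1
B01,R102,2024-05-01,OBS1,1,office,none,0,,0,1,0,0,0,0,1,,1,0,0,0,0,1,,1,0,0,0,0,1,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,,dmat-csv-1
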