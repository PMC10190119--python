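building_id,room_id,date,observer_id,ceiling_total,walls_total,floor_total,windows_total,furnishings_total,hvac_total,supplies_materials_total,pipes_total,room_total,damage_stain_avg,visible_mold_avg,wet_damp_avg,room_average,odor_score,n_components,color_band
B01,R101,2024-05-01,OBS1,2,2,0,1,,,,,6,0.750000,0.250000,0.250000,2.250000,1,4,yellow
B01,R102,2024-05-01,OBS1,0,0,0,,,,,,0,0.000000,0.000000,0.000000,0.000000,0,3,none
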