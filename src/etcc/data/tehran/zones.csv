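site_name,use_type,class_label,area_m2,space_per_visitor_m2,area_ha_reported
Lar national park,extensive,1,4430300,2500,442.9
Lar national park,extensive,2,5566100,2500,557.1
Jajrud protected area,extensive,1,2858000,2500,286.2
Jajrud protected area,extensive,2,4422000,2500,441.8
Jajrud protected area,intensive,1,112600,1500,11.0
Jajrud protected area,intensive,2,88500,1500,8.8
Tangeh Vashi natural monument,extensive,1,18500,2500,1.8
Tangeh Vashi natural monument,extensive,2,34700,2500,3.4
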