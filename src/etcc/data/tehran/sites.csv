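name,total_area_ha,guardians_count,guard_stations,operating_days,availability_hours,average_visit_hours,established_year,reported_annual_visitors
Lar national park,35765,14,4,109,8,8,2001,36000
Jajrud protected area,74811,28,7,365,8,8,1982,50000
Tangeh Vashi natural monument,3650,4,1,155,8,8,2011,300000
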