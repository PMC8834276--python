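site_name,station_name,elevation_m,latitude,longitude,code,magnitude,unit,total
Lar national park,Damavand Synoptic,2051,35d43m00s,52d03m00s,Cf1,12,days,
Lar national park,Damavand Synoptic,2051,35d43m00s,52d03m00s,Cf2,3,days,
Lar national park,Damavand Synoptic,2051,35d43m00s,52d03m00s,Cf3,4,days,
Lar national park,Damavand Synoptic,2051,35d43m00s,52d03m00s,Cf4,12,days,
Lar national park,Damavand Synoptic,2051,35d43m00s,52d03m00s,Cf5,57,days,
Lar national park,Damavand Synoptic,2051,35d43m00s,52d03m00s,Cf6,2,days,
Lar national park,Damavand Synoptic,2051,35d43m00s,52d03m00s,Cf7,2717,hours,
Lar national park,Damavand Synoptic,2051,35d43m00s,52d03m00s,Cf8,42,days,
Jajrud protected area,Lavasan Synoptic,1863,35d49m54s,51d38m33s,Cf1,19,days,
Jajrud protected area,Lavasan Synoptic,1863,35d49m54s,51d38m33s,Cf2,15,days,
Jajrud protected area,Lavasan Synoptic,1863,35d49m54s,51d38m33s,Cf3,10,days,
Jajrud protected area,Lavasan Synoptic,1863,35d49m54s,51d38m33s,Cf4,25,days,
Jajrud protected area,Lavasan Synoptic,1863,35d49m54s,51d38m33s,Cf5,116,days,
Jajrud protected area,Lavasan Synoptic,1863,35d49m54s,51d38m33s,Cf6,3,days,
Jajrud protected area,Lavasan Synoptic,1863,35d49m54s,51d38m33s,Cf7,2833,hours,
Jajrud protected area,Lavasan Synoptic,1863,35d49m54s,51d38m33s,Cf8,49,days,
Tangeh Vashi natural monument,Firuzkooh Synoptic,1976,35d45m00s,52d44m00s,Cf1,15,days,
Tangeh Vashi natural monument,Firuzkooh Synoptic,1976,35d45m00s,52d44m00s,Cf2,2,days,
Tangeh Vashi natural monument,Firuzkooh Synoptic,1976,35d45m00s,52d44m00s,Cf3,4,days,
Tangeh Vashi natural monument,Firuzkooh Synoptic,1976,35d45m00s,52d44m00s,Cf4,11,days,
Tangeh Vashi natural monument,Firuzkooh Synoptic,1976,35d45m00s,52d44m00s,Cf5,144,days,
Tangeh Vashi natural monument,Firuzkooh Synoptic,1976,35d45m00s,52d44m00s,Cf6,3,days,
Tangeh Vashi natural monument,Firuzkooh Synoptic,1976,35d45m00s,52d44m00s,Cf7,3010,hours,
Tangeh Vashi natural monument,Firuzkooh Synoptic,1976,35d45m00s,52d44m00s,Cf8,24,days,
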