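dimension,item_id,label,n,mean,sd,variance,rank
environmental-physical,EP01,Destruction of the habitat and ecosystem,33,4.32,1.000,2.000,1
environmental-physical,EP02,Extinction of biologically valuable species (fauna and flora),33,4.26,1.000,1.060,2
environmental-physical,EP03,Increase in wildlife hunting,33,3.21,1.000,1.000,13
environmental-physical,EP04,Change of the wildlife species' diet and their migration path,33,3.16,1.000,2.030,14
environmental-physical,EP05,Reduction and loss of vegetation covers,33,4.11,1.000,1.000,3
environmental-physical,EP06,"Change in the ecosystem function (flow of matter, energy and information, etc.)",33,3.08,1.000,1.000,15
environmental-physical,EP07,Decrease in biodiversity,33,3.86,1.000,1.000,4
environmental-physical,EP08,Decrease in ecosystem services,33,3.72,1.030,2.000,6
environmental-physical,EP09,Decrease in natural resources,33,3.76,1.000,2.055,5
environmental-physical,EP10,Increase in environmental pollution,33,3.68,1.000,1.000,7
environmental-physical,EP11,Decrease in the reservoirs of groundwater aquifers and a change in the surface water regime,33,3.57,1.000,1.000,8
environmental-physical,EP12,Increase in climate change,33,3.48,1.000,1.000,9
environmental-physical,EP13,Change in biogeochemical cycles,33,2.63,1.000,1.000,21
environmental-physical,EP14,Increase in the water evaporation level,33,2.68,1.000,1.000,20
environmental-physical,EP15,Increase in the soil erosion level,33,3.31,1.000,1.000,11
environmental-physical,EP16,Increase in the LULC changes for the development of tourism infrastructure,33,3.35,1.029,2.000,10
environmental-physical,EP17,Disturbance of landscape,33,3.27,1.000,1.060,12
environmental-physical,EP18,Increase in garbage per visitor,33,2.94,1.000,1.000,17
environmental-physical,EP19,Changes in the quality of local services,33,3.02,1.029,1.043,16
environmental-physical,EP20,"Increase in abrupt environmental crises (such as storms, floods, and earthquakes)",33,2.77,1.000,1.000,19
environmental-physical,EP21,Increase in the congestion in roads and public places,33,2.85,1.029,1.000,18
socio-cultural,SC01,Increase in crime and insecurity,33,3.84,1.000,2.030,1
socio-cultural,SC02,Increase in accidents,33,2.71,1.000,1.000,8
socio-cultural,SC03,Destruction of cultural-historical and ancient monuments,33,3.46,1.000,1.000,4
socio-cultural,SC04,Changes in the culture of local communities,33,3.31,1.000,1.000,5
socio-cultural,SC05,Dissatisfaction in local communities,33,3.57,1.000,2.000,3
socio-cultural,SC06,Increase in cultural invasions,33,3.68,1.000,2.055,2
socio-cultural,SC07,Changes in quality of life standards,33,3.16,1.029,1.000,6
socio-cultural,SC08,Increase in diseases,33,2.88,1.000,1.000,7
economic-institutional,EI01,"Increase in taxes on land, buildings, and other structures",33,3.62,1.000,1.000,2
economic-institutional,EI02,Increase in inflation,33,3.78,1.029,1.000,1
economic-institutional,EI03,"Increase in the demand for public services (such as health, security, and police)",33,2.53,1.000,1.000,7
economic-institutional,EI04,Increase in the demand for economic infrastructure,33,2.67,1.000,1.000,6
economic-institutional,EI05,Increase in tourism costs,33,3.11,1.000,1.000,4
economic-institutional,EI06,Increase in seasonal employees in tourism,33,2.95,1.000,1.000,5
economic-institutional,EI07,Increase in economic pressures on households,33,3.34,1.000,1.000,3
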