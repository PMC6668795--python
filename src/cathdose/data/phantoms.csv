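reference_age_class,nominal_age,reference_height,reference_weight,trunk_semi_axis_ap,trunk_semi_axis_lat,heart_offset_ap,heart_offset_lat,heart_offset_cc
newborn,0,50.9,3.51,4.9,5.5,0,0,0
1y,1,74.4,9.36,6.0,7.0,0,0,0
5y,5,109.1,19.1,7.0,8.5,0,0,0
10y,10,139.8,32.15,8.0,10.0,0,0,0
15y,15,168.1,56.34,9.5,12.0,0,0,0
adult,20,178.6,73.2,10.0,13.0,0,0,0
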