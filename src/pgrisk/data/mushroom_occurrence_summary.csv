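variety,analyte,n_samples,n_detected,min_detected_mg_kg,max_mg_kg,mean_mg_kg,median_mg_kg
A. aegerita,chlormequat,15,8,,0.206,0.064,0.061
A. aegerita,mepiquat chloride,15,14,,4.611,1.602,0.351
A. aegerita,thidiazuron,15,2,,0.054,0.006,0.000
A. aegerita,sodium nitrophenolate,15,5,,0.267,0.052,0.000
A. auricula,sodium nitrophenolate,15,12,,0.207,0.112,0.115
L. edodes,chlormequat,15,10,,0.074,0.041,0.054
P. eryngii,chlormequat,15,1,,0.044,0.003,0.000
P. eryngii,thidiazuron,15,1,,0.020,0.001,0.000
P. eryngii,sodium nitrophenolate,15,4,,0.008,0.001,0.000
P. ostreatus,chlormequat,15,9,,0.633,0.094,0.007
P. ostreatus,mepiquat chloride,15,9,,2.466,0.358,0.059
P. ostreatus,thidiazuron,15,3,,0.050,0.008,0.000
P. ostreatus,sodium nitrophenolate,15,5,,0.093,0.008,0.000
T. fuciformis,chlormequat,15,15,0.156,2.812,1.135,1.261
T. fuciformis,mepiquat chloride,15,12,,3.022,1.246,1.322
T. fuciformis,sodium nitrophenolate,15,10,,0.687,0.322,0.378
H. erinaceus,chlormequat,15,12,,3.259,1.130,0.897
H. erinaceus,mepiquat chloride,15,12,,6.308,2.600,3.113
H. erinaceus,thidiazuron,15,2,,0.212,0.026,0.000
H. erinaceus,sodium nitrophenolate,15,14,,0.647,0.479,0.502
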