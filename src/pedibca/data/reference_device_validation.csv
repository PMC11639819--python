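parameter,group,pbca_mean,pbca_sd,tbca_mean,tbca_sd,standard_error,p_value,accuracy_printed
weight,obese,43.501,0.7,42.746,0.3,0.081,0.001,98.23
weight,normal,29.511,3.5,30.473,2.8,0.454,0.03,96.84
bmi,obese,23.976,3.3,24.854,1.6,0.376,0.020,96.47
bmi,normal,15.697,1.6,16.368,0.6,0.177,0.001,95.90
bf,obese,30.309,3.7,31.959,2.5,0.453,0.003,94.84
bf,normal,21.644,2.3,20.954,2.9,0.381,0.039,96.71
ffm,obese,27.473,1.9,26.753,0.6,0.207,0.006,97.31
ffm,normal,22.431,1.08,23.427,2.1,0.243,0.001,95.75
tbw,obese,18.919,3.9,17.379,4.1,0.575,0.008,91.14
tbw,normal,11.304,1.7,11.954,2.6,0.318,0.042,94.56
mm,obese,23.255,2.2,21.461,2.9,0.371,0.001,91.64
mm,normal,15.847,1.5,14.925,1.9,0.254,0.004,93.82
bm,obese,1.065,0.08,1.095,0.04,0.011,0.002,97.26
bm,normal,0.745,0.08,0.863,0.03,0.010,0.001,86.33
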