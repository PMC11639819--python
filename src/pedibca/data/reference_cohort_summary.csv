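parameter,obese_mean,obese_sd,normal_mean,normal_sd,pct_diff_printed,p_value
age,8.441,0.501,8.061,0.011,4.605,0.003
weight,43.501,0.707,29.511,3.535,38.322,0.001
height,126.511,3.355,125.188,2.828,1.051,0.034
bmi,23.976,3.392,15.697,1.639,41.736,0.001
bf,31.309,3.709,21.644,2.378,37.504,0.001
ffm,27.473,1.962,22.431,1.084,20.206,0.002
tbw,18.919,3.976,11.304,1.727,30.392,0.001
mm,23.255,2.221,15.847,1.577,36.891,0.001
bm,1.065,0.089,0.745,0.087,35.359,0.002
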