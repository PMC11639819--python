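variable,device,pct_mean_difference,ci_low,ci_high,p_value,sem,md,relative_reliability,rr_ci_low,rr_ci_high,inter_rater_icc,irr_ci_low,irr_ci_high
weight,PBCA,3.49,2.96,4.01,0.12,0.38,1.05,1.78,0.78,2.78,0.95,0.93,0.96
weight,TBCA,3.97,3.37,4.57,0.05,0.49,1.35,2.21,1.21,3.21,0.95,0.93,0.96
bmi,PBCA,8.12,7.47,8.76,0.06,0.47,1.29,4.11,3.11,5.11,0.94,0.93,0.96
bmi,TBCA,6.24,5.30,7.18,0.05,0.42,1.18,3.60,2.60,4.60,0.94,0.93,0.96
bf,PBCA,0.07,-0.06,0.12,0.88,0.05,0.13,0.31,-0.69,1.31,0.96,0.93,0.96
bf,TBCA,0.25,0.00,0.49,0.59,0.18,0.49,1.12,0.12,2.12,0.96,0.93,0.96
ffm,PBCA,6.74,6.11,7.36,0.07,0.45,1.25,3.40,2.40,4.40,0.95,0.93,0.96
ffm,TBCA,0.02,-0.04,0.09,0.65,0.05,0.13,0.35,-0.65,1.35,0.96,0.93,0.96
tbw,PBCA,3.07,2.79,3.35,0.22,0.2,0.56,2.15,1.15,3.15,0.95,0.93,0.96
tbw,TBCA,-1.93,-2.07,-1.79,0.24,0.1,0.28,1.05,0.05,2.05,0.96,0.93,0.96
mm,PBCA,2.77,2.35,3.19,0.05,0.21,0.58,1.81,0.81,2.81,0.95,0.93,0.96
mm,TBCA,-4.38,-4.75,-4.00,0.23,0.27,0.75,2.33,1.33,3.33,0.95,0.93,0.96
bm,PBCA,3.49,2.97,4.01,0.05,0.01,0.03,1.95,0.95,2.95,0.95,0.93,0.96
bm,TBCA,1.16,1.15,1.17,0.69,0.01,0.02,1.39,0.39,2.39,0.96,0.93,0.96
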