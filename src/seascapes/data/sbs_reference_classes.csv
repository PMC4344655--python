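class_id,sbs_percent,avg_sst_mean,avg_sst_sd,max_sst_mean,max_sst_sd,min_sst_mean,min_sst_sd,chla_mean,chla_sd,currents_mean,currents_sd,salinity_mean,salinity_sd
1,2.40,26.61,0.70,28.79,0.83,24.78,0.64,1.33,1.84,0.16,0.11,34.04,0.26
2,32.30,27.68,0.29,29.49,0.24,25.81,0.32,0.36,0.29,0.19,0.06,34.23,0.13
3,0,27.23,0.52,30.50,0.48,25.15,0.50,1.54,1.25,0.06,0.05,34.59,0.15
4,13.30,28.06,0.21,30.18,0.30,26.37,0.21,0.33,0.44,0.14,0.05,34.42,0.13
5,34.80,28.23,0.20,29.59,0.20,26.74,0.37,0.23,0.10,0.33,0.06,33.99,0.18
6,12.90,28.29,0.25,29.59,0.23,27.23,0.33,0.31,0.45,0.19,0.09,33.50,0.25
7,2.90,28.79,0.36,29.40,0.26,27.94,0.53,0.48,0.89,0.19,0.09,34.24,0.12
8,1.30,29.06,0.35,29.81,0.32,28.42,0.40,0.41,0.92,0.20,0.08,33.51,0.21
9,0.10,28.55,0.23,29.65,0.23,27.71,0.34,1.40,2.89,0.11,0.07,32.54,0.30
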