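enzyme_label,dp,kcat_per_s,kcat_se,km_mM,km_se,spec_mM_s,spec_se
PcBxl3,2,1.81,0.05,0.90,0.06,2.0,0.2
PcBxl3,3,1.80,0.06,1.14,0.08,1.6,0.2
PcBxl3,4,2.05,0.05,0.74,0.04,2.8,0.2
PcBxl3,5,1.66,0.15,1.21,0.25,1.4,0.3
TrXyl3A,2,0.34,0.01,0.090,0.010,3.7,0.6
TrXyl3A,3,0.39,0.01,0.024,0.005,16,4
TrXyl3A,4,0.82,0.03,0.070,0.010,12,2
TrXyl3A,5,0.56,0.01,0.066,0.003,8.5,0.5
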