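antibody_nm,tracer_nm,b_mean,b_sd,kd_nm,kd_sd_nm
9.6,5.0,0.94,0.014,0.11,0.01
4.8,5.0,0.78,0.012,0.72,0.05
2.4,5.0,0.41,0.007,1.96,0.17
2.4,2.5,0.86,0.060,0.10,0.06
2.4,10.0,0.36,0.001,0.81,0.07
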