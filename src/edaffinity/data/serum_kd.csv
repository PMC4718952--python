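serum,drug,kd_nm,kd_sd_nm,classification
6-AcMorHap,6-AM,0.563,0.05,quantifiable
6-AcMorHap,morphine,0.555,0.08,quantifiable
6-PrOxyHap,6-AM,1.20,0.19,quantifiable
6-PrOxyHap,morphine,1.40,0.16,quantifiable
MorHap,6-AM,2.94,0.34,quantifiable
MorHap,morphine,1.88,0.46,quantifiable
DiAmHap,6-AM,,,low_affinity
DiAmHap,morphine,,,no_binding
DiPrOxyHap,6-AM,,,low_affinity
DiPrOxyHap,morphine,,,no_binding
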