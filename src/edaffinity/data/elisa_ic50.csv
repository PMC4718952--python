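serum,titer,drug,ic50_um,censored,censor_limit_um,note
6-AcMorHap,819200,heroin,0.5,False,,
6-AcMorHap,819200,6-AM,1.1,False,,
6-AcMorHap,819200,morphine,0.1,False,,
6-PrOxyHap,409600,heroin,2.2,False,,
6-PrOxyHap,409600,6-AM,7.5,False,,
6-PrOxyHap,409600,morphine,1.6,False,,
MorHap,1638400,heroin,,True,1000,
MorHap,1638400,6-AM,21.4,False,,
MorHap,1638400,morphine,9.182,False,,run-together typesetting; prose value 9.2
DiAmHap,204800,heroin,,True,1000,
DiAmHap,204800,6-AM,,True,1000,
DiAmHap,204800,morphine,,True,1000,
DiPrOxyHap,102400,heroin,16.8,False,,
DiPrOxyHap,102400,6-AM,144.9,False,,
DiPrOxyHap,102400,morphine,,True,1000,
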