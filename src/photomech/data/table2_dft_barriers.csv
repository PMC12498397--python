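complex,dE_MLCT_MC,dE_MLCT_TS
Ru1,9.96,11.89
Ru2,3.12,5.24
Ru3,-1.72,0.83
Ru4,5.68,8.43
Ru5,5.35,7.39
Ru6,5.81,7.42
Ru7,4.62,7.00
Ru8,4.23,6.54
Ru9,12.31,14.54
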