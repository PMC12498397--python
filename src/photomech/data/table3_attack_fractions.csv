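complex,cis_pct,trans_pct
Ru1,38.7,61.3
Ru2,75.1,24.9
Ru3,48.5,51.5
Ru4,4.2,95.8
Ru5,74.0,26.0
Ru6,33.2,66.8
Ru7,33.6,66.4
Ru8,14.2,85.8
Ru9,62.7,37.3
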