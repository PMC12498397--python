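complex,planarity_mu_deg
Ru1,12.1
Ru7,69.0
Ru8,47.1
Ru9,58.7
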