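complex,lambda_abs_nm,lambda_em_nm,eps_515,phi_515,xi_515,eps_625,phi_625,xi_625,phi_P,phi_1O2
Ru1,490,733,4140,,,1018,,,0.00146,0.045
Ru2,473,632,3040,0.0009,3,76,0.0005,0.04,0.00011,0.001
Ru3,470,664,1850,0.0010,2,26,0.0061,2,0.00104,0.001
Ru4,477,691,2880,0.0004,1,355,0.0005,0.2,0.00249,0.001
Ru5,471,652,2830,0.0007,2,32,0.0025,0.08,0.00178,0.001
Ru6,475,676,2360,0.0008,2,279,0.0008,0.2,0.00196,0.001
Ru7,485,687,3180,0.0056,18,509,0.0067,3.4,0.00101,0.027
Ru8,487,700,3120,0.0063,20,580,0.0091,5.3,0.00109,0.019
Ru9,487,688,3610,0.0043,16,329,0.0077,2.5,0.00145,0.025
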