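target,source
Fp1,E22
Fp2,E9
F7,E33
F3,E24
Fz,E11
F4,E124
F8,E122
T7,E45
C3,E36
Cz,Cz
C4,E104
T8,E108
P7,E58
P3,E52
Pz,E62
P4,E92
P8,E96
O1,E70
O2,E83
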