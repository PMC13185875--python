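code,sigma_p
H,0.00
F,0.06
Cl,0.23
Br,0.23
I,0.18
NH2,-0.66
OH,-0.37
OMe,-0.27
SH,0.15
SMe,0.00
NO2,0.78
CN,0.66
CHO,0.42
COOH,0.45
CH3,-0.17
CCH,0.23
CCPh,0.16
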