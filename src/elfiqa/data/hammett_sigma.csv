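substituent,sigma_m,sigma_p
H,0.00,0.00
CH3,-0.07,-0.17
NH2,-0.16,-0.66
NH3+,0.86,0.60
NO2,0.71,0.78
O-,-0.47,-0.81
F,0.34,0.06
Cl,0.37,0.23
Br,0.39,0.23
CN,0.56,0.66
CF3,0.43,0.54
SH,0.25,0.15
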