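# Soft-tissue elemental composition (percent by weight) and density.
# density_g_cm3 = 1.04
element,percent_by_weight
H,10.454
C,22.663
N,2.49
O,63.525
Na,0.112
Mg,0.013
Si,0.03
P,0.134
S,0.204
Cl,0.133
K,0.208
Ca,0.024
Fe,0.005
Zn,0.003
Rb,0.001
Zr,0.001
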