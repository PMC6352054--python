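# Self-doses (uGy per MBq.s) vs the OLINDA/EXM sphere model for
# P-32, Y-90, Cl-38. Reference fixture only.
nuclide,volume_cm3,comparison,dose,dose_olinda,diff_printed_pct,flags
Cl-38,67.02,amato,2.69,3.33,-19.21,
Cl-38,67.02,this_study,3.18,3.33,-4.5,
P-32,6.28,amato,14.1,16.2,-12.96,
P-32,6.28,this_study,15.38,16.2,-5.11,
Y-90,6.28,amato,17.02,20.81,-18.21,
Y-90,6.28,this_study,20.67,20.81,-0.67,
Cl-38,6.28,amato,19.58,28.4,-31.05,
Cl-38,6.28,this_study,33.2,28.4,16.9,
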