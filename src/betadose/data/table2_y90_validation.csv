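# Y-90 sphere validation: absorbed fractions, this work vs previously published.
# sigma_printed_pct is the printed 100*(this-ref) statistic; sign_suspect rows
# recompute with the opposite sign and are stored as printed.
energy_mode,radius_cm,volume_cm3,phi_this_work,phi_reference,reference_source,sigma_printed_pct,flags
mean,0.1,0.004,0.15,0.16,Akabani,-1.0,
mean,0.25,0.065,0.45,0.48,Akabani,-3.0,
mean,1.0,4.0,0.84,0.86,Akabani,-2.0,
spectrum,0.1,0.004,0.16,0.17,Akabani,-1.0,
spectrum,0.25,0.065,0.36,0.39,Akabani,-3.0,
spectrum,1.0,4.0,0.75,0.8,Akabani,-5.0,
spectrum,1.33,10.0,0.8,0.85,Amato,-5.0,
spectrum,1.68,20.0,0.9,0.88,Amato,-2.0,sign_suspect
spectrum,2.87,100.0,0.94,0.93,Amato,1.0,
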