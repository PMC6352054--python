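# Beta-decay branch library: endpoint energies (MeV), daughter atomic
# number (signed: positive = beta-minus), intensities per decay, and
# forbiddenness class ('allowed' or '1u' = unique first-forbidden).
# Values compiled from standard decay-data evaluations (ENSDF/ICRP-107 class).
nuclide,branch,Q_MeV,daughter_Z,intensity,forbiddenness
C-14,1,0.156476,7,1.0,allowed
Au-199,1,0.2441,80,0.215,allowed
Au-199,2,0.2957,80,0.719,allowed
Au-199,3,0.4527,80,0.066,allowed
Lu-177,1,0.1766,72,0.121,allowed
Lu-177,2,0.2486,72,0.002,allowed
Lu-177,3,0.3849,72,0.090,allowed
Lu-177,4,0.4983,72,0.787,allowed
I-131,1,0.2478,54,0.0212,allowed
I-131,2,0.3038,54,0.0062,allowed
I-131,3,0.3339,54,0.0727,allowed
I-131,4,0.6063,54,0.896,allowed
I-131,5,0.8069,54,0.004,allowed
Sr-90,1,0.546,39,1.0,1u
Sm-153,1,0.6344,63,0.313,allowed
Sm-153,2,0.7045,63,0.497,allowed
Sm-153,3,0.8081,63,0.179,allowed
Re-186,1,0.9324,76,0.216,allowed
Re-186,2,1.0695,76,0.709,allowed
P-32,1,1.7106,16,1.0,allowed
Y-90,1,2.2801,40,0.9998,1u
Cl-38,1,1.1067,18,0.319,allowed
Cl-38,2,2.749,18,0.105,allowed
Cl-38,3,4.9165,18,0.576,1u
Rb-88,1,1.658,38,0.035,allowed
Rb-88,2,2.578,38,0.134,allowed
Rb-88,3,5.313,38,0.768,1u
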