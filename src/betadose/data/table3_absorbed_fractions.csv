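# Absorbed fractions from full-spectrum vs mean-energy beta transport,
# 11 nuclides x 3 shapes x 4 volumes. sigma_printed_pct is the printed
# relative percent difference; flagged cells are stored as printed.
nuclide,shape,volume_cm3,phi_spectrum,unc_spectrum,phi_mean,unc_mean,sigma_printed_pct,flags
C-14,sphere,0.01,0.9,0.02,0.986,0.01,-8.72,
C-14,sphere,1.0,0.92,0.02,0.997,0.01,-7.72,
C-14,sphere,100.0,0.924,0.02,0.999,0.01,-7.51,
C-14,sphere,200.0,0.925,0.02,1.0,0.01,-7.5,
C-14,prolate,0.01,0.898,0.02,0.985,0.01,-8.83,
C-14,prolate,1.0,0.92,0.02,0.994,0.01,-7.42,recompute_mismatch
C-14,prolate,100.0,0.924,0.02,0.999,0.01,-7.51,
C-14,prolate,200.0,0.924,0.02,0.999,0.01,-7.51,
C-14,oblate,0.01,0.898,0.02,0.985,0.01,-8.83,
C-14,oblate,1.0,0.92,0.02,0.997,0.01,-7.72,
C-14,oblate,100.0,0.924,0.02,0.999,0.01,-7.51,
C-14,oblate,200.0,0.924,0.02,0.999,0.01,-7.51,
Au-199,sphere,0.01,0.821,0.03,0.964,0.01,-14.83,
Au-199,sphere,1.0,0.88,0.03,0.992,0.01,-11.29,
Au-199,sphere,100.0,0.892,0.03,0.998,0.01,-10.62,
Au-199,sphere,200.0,0.893,0.03,0.999,0.01,-10.61,
Au-199,prolate,0.01,0.815,0.03,0.961,0.01,-15.19,
Au-199,prolate,1.0,0.855,0.03,0.992,0.01,-13.81,
Au-199,prolate,100.0,0.893,0.03,0.998,0.01,-10.52,
Au-199,prolate,200.0,0.893,0.03,0.999,0.01,-10.61,
Au-199,oblate,0.01,0.814,0.03,0.96,0.01,-15.21,
Au-199,oblate,1.0,0.878,0.03,0.992,0.01,-11.49,
Au-199,oblate,100.0,0.893,0.03,0.998,0.01,-10.52,
Au-199,oblate,200.0,0.893,0.03,0.999,0.01,-10.61,
Lu-177,sphere,0.01,0.774,0.02,0.927,0.01,-16.5,
Lu-177,sphere,1.0,0.885,0.03,0.984,0.01,-10.06,
Lu-177,sphere,100.0,0.91,0.03,0.997,0.01,-8.72,
Lu-177,sphere,200.0,0.911,0.03,0.997,0.01,-8.62,
Lu-177,prolate,0.01,0.763,0.02,0.92,0.01,-17.06,
Lu-177,prolate,1.0,0.883,0.03,0.983,0.01,-10.17,
Lu-177,prolate,100.0,0.91,0.03,0.996,0.01,-8.63,
Lu-177,prolate,200.0,0.911,0.03,0.997,0.01,-8.53,recompute_mismatch
Lu-177,oblate,0.01,0.761,0.02,0.919,0.01,-17.19,
Lu-177,oblate,1.0,0.882,0.03,0.983,0.01,-10.27,
Lu-177,oblate,100.0,0.91,0.03,0.996,0.01,-8.63,
Lu-177,oblate,200.0,0.911,0.03,0.997,0.01,-8.62,
I-131,sphere,0.01,0.705,0.02,0.882,0.01,-20.06,
I-131,sphere,1.0,0.857,0.03,0.974,0.01,-12.01,
I-131,sphere,100.0,0.891,0.03,0.994,0.01,-10.36,
I-131,sphere,200.0,0.893,0.03,0.996,0.01,-10.34,
I-131,prolate,0.01,0.692,0.02,0.871,0.01,-20.55,
I-131,prolate,1.0,0.854,0.03,0.972,0.01,-12.14,
I-131,prolate,100.0,0.891,0.03,0.994,0.01,-10.36,
I-131,prolate,200.0,0.893,0.03,0.995,0.01,-10.25,
I-131,oblate,0.01,0.688,0.02,0.869,0.01,-20.82,
I-131,oblate,1.0,0.853,0.03,0.972,0.01,-12.24,
I-131,oblate,100.0,0.891,0.03,0.994,0.01,-10.36,
I-131,oblate,200.0,0.893,0.03,0.995,0.01,-10.25,
Sr-90,sphere,0.01,0.726,0.02,0.865,0.01,-16.06,
Sr-90,sphere,1.0,0.886,0.02,0.967,0.01,-8.37,
Sr-90,sphere,100.0,0.923,0.03,0.991,0.01,-6.86,
Sr-90,sphere,200.0,0.925,0.03,0.993,0.01,-6.85,
Sr-90,prolate,0.01,0.711,0.02,0.852,0.01,-16.54,
Sr-90,prolate,1.0,0.883,0.02,0.965,0.01,-8.49,
Sr-90,prolate,100.0,0.923,0.03,0.99,0.01,-6.76,
Sr-90,prolate,200.0,0.925,0.03,0.991,0.01,-6.65,
Sr-90,oblate,0.01,0.708,0.02,0.85,0.01,-16.7,
Sr-90,oblate,1.0,0.883,0.02,0.965,0.01,-8.49,
Sr-90,oblate,100.0,0.923,0.03,0.99,0.01,-6.76,
Sr-90,oblate,200.0,0.925,0.03,0.992,0.01,-6.75,
Sm-153,sphere,0.01,0.657,0.02,0.832,0.02,-21.03,
Sm-153,sphere,1.0,0.855,0.03,0.962,0.01,-11.12,
Sm-153,sphere,100.0,0.901,0.03,0.991,0.01,-9.08,
Sm-153,sphere,200.0,0.904,0.03,0.992,0.01,-8.87,
Sm-153,prolate,0.01,0.64,0.02,0.816,0.02,-21.57,
Sm-153,prolate,1.0,0.85,0.02,0.959,0.01,-11.36,
Sm-153,prolate,100.0,0.901,0.03,0.989,0.01,-8.89,
Sm-153,prolate,200.0,0.904,0.03,0.992,0.01,-8.87,
Sm-153,oblate,0.01,0.636,0.02,0.813,0.02,-21.77,
Sm-153,oblate,1.0,0.849,0.02,0.958,0.01,-11.37,
Sm-153,oblate,100.0,0.9,0.03,0.988,0.01,-8.91,
Sm-153,oblate,200.0,0.903,0.03,0.992,0.01,-8.97,
Re-186,sphere,0.01,0.555,0.02,0.717,0.02,-22.59,
Re-186,sphere,1.0,0.834,0.02,0.937,0.01,-10.99,
Re-186,sphere,100.0,0.894,0.03,0.986,0.01,-9.33,
Re-186,sphere,200.0,0.902,0.03,0.989,0.01,-8.79,
Re-186,prolate,0.01,0.555,0.02,0.697,0.02,-20.37,
Re-186,prolate,1.0,0.832,0.02,0.932,0.01,-10.73,
Re-186,prolate,100.0,0.893,0.03,0.985,0.01,-9.34,
Re-186,prolate,200.0,0.902,0.03,0.988,0.01,-8.7,
Re-186,oblate,0.01,0.552,0.02,0.692,0.02,-20.23,
Re-186,oblate,1.0,0.832,0.02,0.93,0.01,-10.54,
Re-186,oblate,100.0,0.892,0.03,0.985,0.01,-9.44,
Re-186,oblate,200.0,0.899,0.03,0.988,0.01,-9.01,
P-32,sphere,0.01,0.295,0.01,0.337,0.01,12.46,sign_suspect
P-32,sphere,1.0,0.734,0.02,0.827,0.02,-11.24,
P-32,sphere,100.0,0.895,0.02,0.961,0.02,-6.86,
P-32,sphere,200.0,0.904,0.02,0.969,0.02,-6.71,
P-32,prolate,0.01,0.282,0.02,0.306,0.02,-7.84,
P-32,prolate,1.0,0.718,0.02,0.813,0.02,-11.68,
P-32,prolate,100.0,0.891,0.02,0.956,0.02,-6.79,
P-32,prolate,200.0,0.902,0.02,0.967,0.02,-6.72,
P-32,oblate,0.01,0.28,0.02,0.305,0.02,-8.19,
P-32,oblate,1.0,0.714,0.02,0.81,0.02,-11.85,
P-32,oblate,100.0,0.89,0.02,0.958,0.02,-7.09,
P-32,oblate,200.0,0.901,0.02,0.967,0.02,-6.83,
Y-90,sphere,0.01,0.207,0.01,0.215,0.01,-3.72,
Y-90,sphere,1.0,0.645,0.02,0.755,0.02,-14.56,
Y-90,sphere,100.0,0.872,0.02,0.946,0.02,-7.82,
Y-90,sphere,200.0,0.886,0.02,0.956,0.02,-7.32,
Y-90,prolate,0.01,0.198,0.01,0.204,0.01,-2.94,
Y-90,prolate,1.0,0.624,0.02,0.736,0.02,-15.22,
Y-90,prolate,100.0,0.867,0.02,0.935,0.02,-7.27,
Y-90,prolate,200.0,0.882,0.02,0.95,0.02,-7.16,
Y-90,oblate,0.01,0.197,0.01,0.204,0.01,-3.43,
Y-90,oblate,1.0,0.62,0.02,0.732,0.02,-15.3,
Y-90,oblate,100.0,0.866,0.02,0.931,0.02,-6.98,
Y-90,oblate,200.0,0.881,0.02,0.95,0.02,-7.26,
Cl-38,sphere,0.01,0.121,0.01,0.119,0.01,1.68,
Cl-38,sphere,1.0,0.411,0.02,0.584,0.02,-29.62,
Cl-38,sphere,100.0,0.782,0.03,0.903,0.01,-13.39,
Cl-38,sphere,200.0,0.81,0.03,0.922,0.01,-12.14,
Cl-38,prolate,0.01,0.114,0.01,0.112,0.01,1.78,
Cl-38,prolate,1.0,0.393,0.02,0.556,0.02,-29.32,
Cl-38,prolate,100.0,0.771,0.03,0.896,0.02,-13.95,
Cl-38,prolate,200.0,0.802,0.03,0.917,0.02,-12.54,
Cl-38,oblate,0.01,0.114,0.01,0.112,0.01,1.785,
Cl-38,oblate,1.0,0.391,0.02,0.551,0.02,-29.04,
Cl-38,oblate,100.0,0.769,0.03,0.894,0.02,-13.98,
Cl-38,oblate,200.0,0.8,0.03,0.916,0.02,-12.66,
Rb-88,sphere,0.01,0.09,0.01,0.088,0.01,2.27,
Rb-88,sphere,1.0,0.369,0.02,0.457,0.02,-19.25,
Rb-88,sphere,100.0,0.733,0.02,0.866,0.02,-15.35,monotonicity_suspect
Rb-88,sphere,200.0,0.806,0.02,0.894,0.02,-9.84,
Rb-88,prolate,0.01,0.084,0.01,0.083,0.01,1.2,
Rb-88,prolate,1.0,0.352,0.02,0.428,0.02,-17.75,
Rb-88,prolate,100.0,0.762,0.02,0.857,0.02,-11.08,
Rb-88,prolate,200.0,0.797,0.02,0.886,0.02,-10.04,
Rb-88,oblate,0.01,0.084,0.01,0.083,0.02,1.2,
Rb-88,oblate,1.0,0.35,0.02,0.425,0.02,-17.65,
Rb-88,oblate,100.0,0.76,0.02,0.855,0.02,-11.11,
Rb-88,oblate,200.0,0.795,0.02,0.884,0.02,-10.06,
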