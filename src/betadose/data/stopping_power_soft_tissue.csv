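# Electron collision mass stopping power of soft tissue, computed from
# the Berger-Seltzer/Moller closed form with I = 75 eV and Z/A = 0.5513
# (from the packaged tissue composition); no density-effect correction.
energy_MeV,mass_stopping_power_MeV_cm2_g
0.001,118.959
0.00114834,108.856
0.00131868,99.3883
0.00151428,90.5596
0.0017389,82.3633
0.00199685,74.7836
0.00229305,67.7983
0.00263319,61.3806
0.00302379,55.5007
0.00347233,50.1271
0.0039874,45.2274
0.00457887,40.7691
0.00525808,36.7202
0.00603805,33.0498
0.0069337,29.7278
0.00796222,26.7258
0.0091433,24.017
0.0104996,21.5759
0.0120571,19.379
0.0138455,17.4042
0.0158993,15.6311
0.0182578,14.041
0.0209661,12.6164
0.0240761,11.3416
0.0276474,10.202
0.0317485,9.18432
0.036458,8.27648
0.041866,7.46752
0.0480763,6.74747
0.0552077,6.10733
0.063397,5.53895
0.072801,5.03498
0.0836,4.58881
0.0960009,4.19447
0.110241,3.84662
0.126594,3.54045
0.145372,3.27167
0.166936,3.03644
0.191699,2.83129
0.220135,2.65317
0.252789,2.49932
0.290287,2.36727
0.333346,2.25482
0.382794,2.16
0.439576,2.08101
0.504781,2.01626
0.579658,1.96428
0.665642,1.92375
0.76438,1.89344
0.877766,1.87225
1.00797,1.85915
1.15749,1.85319
1.32918,1.85352
1.52635,1.85933
1.75276,1.86989
2.01276,1.88456
2.31133,1.90273
2.65418,1.92389
3.04789,1.94756
3.5,1.97333
3.78015,1.98846
4.08271,2.00408
4.4095,2.02013
4.76244,2.03658
5.14364,2.05338
5.55534,2.07049
6,2.08789
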