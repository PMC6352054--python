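# Spectrum-integrated self-doses (uGy per MBq.s) vs the prior
# mono-energetic-parameterization model, three sphere volumes.
# Reference fixture only: not an oracle for self_dose_spectrum.
nuclide,volume_cm3,dose_this_study,dose_amato,diff_printed_pct,flags
C-14,6.28,2.527,2.706,-6.61,
C-14,67.03,0.237,0.259,-8.49,
C-14,753.97,0.021,0.023,-8.69,
Au-199,6.28,1.941,2.123,8.57,sign_suspect
Au-199,67.03,0.182,0.2,-9.0,
Au-199,753.97,0.016,0.018,-11.11,
Lu-177,6.28,2.959,3.212,-7.87,
Lu-177,67.03,0.277,0.305,-9.18,
Lu-177,753.97,0.025,0.027,-7.41,
I-131,6.28,4.037,4.341,-7.0,
I-131,67.03,0.378,0.415,-8.91,
I-131,753.97,0.034,0.037,-8.11,
Sr-90,6.28,4.346,4.673,-6.99,
Sr-90,67.03,0.407,0.447,-8.94,
Sr-90,753.97,0.036,0.04,-10.0,
Sm-153,6.28,5.05,5.368,-5.92,
Sm-153,67.03,0.473,0.518,-8.68,
Sm-153,753.97,0.042,0.046,-8.69,
Re-186,6.28,7.278,7.45,-2.31,
Re-186,67.03,0.682,0.738,-7.58,
Re-186,753.97,0.061,0.067,-8.95,
P-32,6.28,15.376,14.102,9.03,
P-32,67.03,1.441,1.507,-4.37,
P-32,753.97,0.128,0.14,-8.57,
Y-90,6.28,20.675,17.024,21.44,
Y-90,67.03,1.938,1.948,-0.51,
Y-90,753.97,0.172,0.185,-7.02,
Cl-38,6.28,33.897,19.584,73.08,
Cl-38,67.03,3.177,2.689,18.15,
Cl-38,753.97,0.282,0.285,-1.05,
Rb-88,6.28,45.714,23.641,93.36,
Rb-88,67.03,4.285,3.451,24.17,
Rb-88,753.97,0.381,0.377,-1.06,sign_suspect
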