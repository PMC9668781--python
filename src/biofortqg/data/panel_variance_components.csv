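trait,mean,h2,h2m,sigma2_g,sigma2_ge,sigma2_e,chi2_g,chi2_ge,g_significant,ge_significant
TCC,4.09,0.72,1.00,5.44,0.00,2.16,100.36,0.00,1,0
DMC.Grav,34.22,0.45,0.92,5.26,3.87,2.59,852.71,288.62,1,1
DMC.OD,39.99,0.54,0.98,13.15,1.68,9.44,48.74,0.02,1,0
FRY,16.49,0.21,0.83,17.28,28.06,37.56,281.36,209.28,1,1
ShY,18.57,0.22,0.81,19.12,35.14,32.50,287.30,305.41,1,1
HI,45.40,0.32,0.89,49.42,46.83,56.40,532.64,151.22,1,1
DRY,5.06,0.21,0.80,1.78,3.49,3.22,203.33,227.16,1,1
NRP,4.15,0.32,0.89,0.81,0.80,0.89,41.30,31.24,1,1
StC,25.36,0.48,1.00,5.17,0.00,5.59,15.26,0.00,1,0
HCN,6.80,0.60,0.96,1.60,0.53,0.52,128.22,150.61,1,1
PulpColor,2.11,0.42,0.99,0.18,0.00,0.25,31.61,0.00,1,0
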