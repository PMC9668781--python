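genotype_id,cluster,DMC.Grav,DMC.OD,TCC,FRY,ShY,HI,DRY,NRP,StC,PulpColor,HCN
Folha-Fina,4,35.91,37.84,3.32,32.86,31.47,47.96,9.79,4.91,25.03,2.07,2.89
BGM-1390,4,38.18,41.59,4.56,26.9,35.0,46.95,9.79,6.99,25.85,3.04,7.33
BGM-1962,4,35.3,39.15,9.85,24.31,23.77,47.32,7.78,4.09,25.54,2.68,7.4
BGM-0597,3,32.8,42.16,13.08,17.94,21.97,42.99,4.82,4.71,25.99,2.86,7.26
BGM-2127,4,33.4,36.44,3.26,32.9,18.61,62.69,14.81,4.75,21.97,1.14,5.49
CPAFRO-04,6,38.01,42.73,7.53,23.67,18.0,57.82,7.09,3.92,26.35,2.99,7.46
BGM-0019,3,36.05,44.1,11.67,17.15,20.47,42.9,5.3,4.26,28.87,2.74,7.23
BGM-1692,4,32.25,39.4,4.51,24.91,23.61,49.85,6.97,4.99,24.32,2.64,4.08
BGM-1700,6,34.81,39.98,9.14,20.06,20.0,49.04,6.46,4.21,25.89,1.91,6.15
BGM-1709,3,33.43,41.43,9.15,20.2,20.9,46.59,5.99,5.72,26.25,2.91,7.38
BGM-0290,4,38.06,43.36,2.57,23.95,23.03,50.4,7.74,3.42,24.7,2.98,4.45
BGM-1835,2,35.09,42.13,2.22,22.02,17.57,56.21,6.86,7.4,27.42,1.94,3.5
BGM-0368,2,33.35,38.18,3.56,21.17,16.55,53.8,5.92,6.11,26.04,2.09,2.46
BGM-2353,6,38.19,43.11,5.88,16.79,16.44,48.88,7.31,2.45,27.99,2.14,3.84
BGM-1745,3,37.51,42.74,8.96,16.08,14.21,50.83,5.51,3.62,29.1,2.94,7.4
BGM-0918,4,36.15,43.11,2.09,32.06,33.27,41.18,10.17,4.23,25.9,1.37,7.08
BGM-0444,2,32.44,37.42,4.61,23.25,22.2,51.45,6.46,3.5,23.93,2.07,3.95
BGM-0901,4,36.4,46.12,2.6,28.41,29.28,46.15,8.73,4.66,26.18,1.85,7.46
BGM-1780,3,37.62,41.61,8.98,15.85,14.44,49.04,5.34,4.2,27.38,3.18,7.4
BGM-0212,2,34.03,44.02,5.5,16.01,16.66,48.87,4.63,4.83,25.92,2.14,2.81
BGM-1814,4,34.47,41.05,3.66,22.15,24.35,48.9,6.51,4.62,28.93,2.0,4.83
BGM-0579,4,36.64,45.66,7.34,21.31,24.46,41.82,6.97,4.85,26.76,1.25,7.32
BRS Dourada,2,31.48,41.94,2.65,24.78,24.28,50.3,6.4,5.79,22.18,2.29,4.18
BGM-0120,4,31.4,34.11,2.07,33.62,34.84,50.7,8.9,5.19,22.67,1.8,7.32
BGM-0659,4,29.77,39.44,5.28,22.97,30.26,42.2,6.11,6.82,23.44,2.25,5.63
BGM-0760,4,32.22,38.93,4.09,25.79,18.32,54.34,7.18,4.72,24.7,2.25,5.63
BRS Gema de Ovo,2,35.75,42.73,3.67,17.9,20.99,46.57,5.61,5.74,25.77,2.31,3.08
BGM-0936,3,33.93,39.58,9.68,16.19,25.49,35.37,5.38,5.0,28.5,3.0,7.41
BGM-1497,2,34.87,35.46,3.56,20.74,16.32,57.14,6.55,3.66,23.25,2.09,2.56
BGM-2345,2,36.09,44.85,3.15,19.21,17.59,52.97,5.75,6.78,23.3,1.89,3.57
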