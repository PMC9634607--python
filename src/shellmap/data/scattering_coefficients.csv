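# Multi-Gaussian atomic scattering factor coefficients, f(s) = sum_k a_k exp(-b_k s^2/4) (+ c), s = 1/d.
# electron: Peng 5-Gaussian elastic electron scattering parametrization (International Tables C, 4.3.2.2).
# xray: International Tables 4-Gaussian + constant (IT92 / Cromer-Mann).
element,kind,a1,a2,a3,a4,a5,b1,b2,b3,b4,b5,c
H,electron,0.0349,0.1201,0.197,0.0573,0.1195,0.5347,3.5867,12.3471,18.9525,38.6269,0
H,xray,0.493002,0.322912,0.140191,0.04081,0,10.5109,26.1257,3.14236,57.7997,0,0.003038
C,electron,0.0893,0.2563,0.757,1.0487,0.3575,0.2465,1.71,6.4094,18.6113,50.2523,0
C,xray,2.31,1.02,1.5886,0.865,0,20.8439,10.2075,0.5687,51.6512,0,0.2156
N,electron,0.1022,0.3219,0.7982,0.8197,0.1715,0.2451,1.7481,6.1925,17.3894,48.1431,0
N,xray,12.2126,3.1322,2.0125,1.1663,0,0.0057,9.8933,28.9975,0.5826,0,-11.529
O,electron,0.0974,0.2921,0.691,0.699,0.2039,0.2067,1.3815,4.6943,12.7105,32.4726,0
O,xray,3.0485,2.2868,1.5463,0.867,0,13.2771,5.7011,0.3239,32.9089,0,0.2508
P,electron,0.2548,0.6106,1.4541,2.3204,0.8477,0.2908,1.874,8.5176,24.3434,63.2996,0
P,xray,6.4345,4.1791,1.78,1.4908,0,1.9067,27.157,0.526,68.1645,0,1.1149
S,electron,0.2497,0.5628,1.3899,2.1865,0.7715,0.2681,1.6711,7.0267,19.5377,50.3888,0
S,xray,6.9053,5.2034,1.4379,1.5863,0,1.4679,22.2151,0.2536,56.172,0,0.8669
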