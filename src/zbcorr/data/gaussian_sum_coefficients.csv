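element,radiation,Z,a1,a2,a3,a4,a5,b1,b2,b3,b4,b5,c,source
H,xray,1,0.489918,0.262003,0.196767,0.049879,,20.6593,7.74039,49.5519,2.20159,,0.001305,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
C,xray,6,2.31000,1.02000,1.58860,0.865000,,20.8439,10.2075,0.568700,51.6512,,0.215600,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
N,xray,7,12.2126,3.13220,2.01250,1.16630,,0.005700,9.89330,28.9975,0.582600,,-11.5290,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
O,xray,8,3.04850,2.28680,1.54630,0.867000,,13.2771,5.70110,0.323900,32.9089,,0.250800,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
Na,xray,11,4.76260,3.17360,1.26740,1.11280,,3.28500,8.84220,0.313600,129.424,,0.676000,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
Mg,xray,12,5.42040,2.17350,1.22690,2.30730,,2.82750,79.2611,0.380800,7.19370,,0.858400,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
Al,xray,13,6.42020,1.90020,1.59360,1.96460,,3.03870,0.742600,31.5472,85.0886,,1.11510,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
Si,xray,14,6.29150,3.03530,1.98910,1.54100,,2.43860,32.3337,0.678500,81.6937,,1.14070,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
P,xray,15,6.43450,4.17910,1.78000,1.49080,,1.90670,27.1570,0.526000,68.1645,,1.11490,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
S,xray,16,6.90530,5.20340,1.43790,1.58630,,1.46790,22.2151,0.253600,56.1720,,0.866900,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
Cl,xray,17,11.4604,7.19640,6.25560,1.64550,,0.010400,1.16620,18.5194,47.7784,,-9.55740,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
Ca,xray,20,8.62660,7.38730,1.58990,1.02110,,10.4421,0.659900,85.7484,178.437,,1.37510,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
Fe,xray,26,11.7695,7.35730,3.52220,2.30450,,4.76110,0.307200,15.3535,76.8805,,1.03690,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
Se,xray,34,17.0006,5.81960,3.97310,4.35430,,2.40980,0.272600,15.2372,43.8163,,2.84090,Cromer-Mann 4-Gaussian International Tables Vol C Table 6.1.1.4
H,electron,1,0.0349,0.1201,0.1970,0.0573,0.1195,0.5347,3.5867,12.3471,18.9525,38.6269,0.0,Peng-Ren-Dudarev-Whelan 5-Gaussian Acta Cryst A52 257 (1996)
C,electron,6,0.0893,0.2563,0.7570,1.0487,0.3575,0.2465,1.7100,6.4094,18.6113,50.2523,0.0,Peng-Ren-Dudarev-Whelan 5-Gaussian Acta Cryst A52 257 (1996)
N,electron,7,0.1022,0.3219,0.7982,0.8197,0.1715,0.2451,1.7481,6.1925,17.3894,48.1431,0.0,Peng-Ren-Dudarev-Whelan 5-Gaussian Acta Cryst A52 257 (1996)
O,electron,8,0.0974,0.2921,0.6910,0.6990,0.2039,0.2067,1.3815,4.6943,12.7105,32.4726,0.0,Peng-Ren-Dudarev-Whelan 5-Gaussian Acta Cryst A52 257 (1996)
P,electron,15,0.2548,0.6106,1.4541,2.3204,0.8477,0.2908,1.8740,8.5176,24.3434,63.2996,0.0,Peng-Ren-Dudarev-Whelan 5-Gaussian Acta Cryst A52 257 (1996)
S,electron,16,0.2497,0.5628,1.3899,2.1865,0.7715,0.2681,1.6711,7.0267,19.5377,50.3888,0.0,Peng-Ren-Dudarev-Whelan 5-Gaussian Acta Cryst A52 257 (1996)
Fe,electron,26,0.3946,1.2725,1.7031,2.3140,1.4795,0.2717,2.0443,7.6007,29.9714,86.2265,0.0,Peng-Ren-Dudarev-Whelan 5-Gaussian Acta Cryst A52 257 (1996)
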