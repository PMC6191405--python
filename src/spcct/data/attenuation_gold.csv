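energy_keV,mu_rho_cm2_g,side
10,113,
15,128,
20,76.2,
30,27.1,
40,12.8,
50,7.19,
60,4.49,
70,2.98,
80.7,2.16,below
80.7,8.9,above
100,5.16,
120,3.19,
150,1.86,
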