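energy_keV,mu_rho_cm2_g,side
10,330,
15,109,
20,49,
30,15.1,
40,7.2,
50.2,3.95,below
50.2,19.1,above
60,11.4,
80,5.05,
100,3,
120,1.93,
150,1.16,
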