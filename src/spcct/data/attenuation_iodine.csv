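energy_keV,mu_rho_cm2_g,side
10,162,
15,55.4,
20,25.36,
30,8.561,
33.2,6.55,below
33.2,35.8,above
40,21.8,
50,12.32,
60,7.579,
80,3.51,
100,1.942,
120,1.22,
150,0.701,
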