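energy_keV,mu_rho_cm2_g,side
10,4.14658,
15,1.32642,
20,0.662576,
30,0.327814,
40,0.244,
50,0.210971,
60,0.193624,
80,0.174567,
100,0.162973,
150,0.144201,
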