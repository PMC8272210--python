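starch,concentration_g_per_g,fat,phase,delta_ea_kj_mol,se_kj_mol
E 1420,0.12,beef,oil,25.7,0.6
E 1420,0.12,pork,oil,23.5,0.2
E 1420,0.12,beef,water,13.0,0.3
E 1420,0.12,pork,water,12.3,0.4
E 1420,0.17,beef,oil,29.5,0.4
E 1420,0.17,pork,oil,27.3,0.3
E 1420,0.17,beef,water,15.8,0.5
E 1420,0.17,pork,water,19.5,0.6
E 1420,0.25,beef,oil,20.2,0.3
E 1420,0.25,pork,oil,17.4,0.7
E 1420,0.25,beef,water,19.5,0.2
E 1420,0.25,pork,water,13.7,0.4
LU 1432,0.12,beef,oil,21.1,0.4
LU 1432,0.12,pork,oil,20.4,0.7
LU 1432,0.12,beef,water,28.9,0.5
LU 1432,0.12,pork,water,22.9,0.2
LU 1432,0.17,beef,oil,27.7,0.5
LU 1432,0.17,pork,oil,22.2,0.3
LU 1432,0.17,beef,water,31.2,0.7
LU 1432,0.17,pork,water,24.4,0.4
LU 1432,0.25,beef,oil,22.1,0.2
LU 1432,0.25,pork,oil,18.8,0.5
LU 1432,0.25,beef,water,10.9,0.6
LU 1432,0.25,pork,water,23.1,0.5
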