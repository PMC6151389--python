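element,mass,electronegativity,polarizability,vdw_radius
H,1.008,2.20,0.667,1.20
B,10.81,2.04,3.03,1.92
C,12.011,2.55,1.76,1.70
N,14.007,3.04,1.10,1.55
O,15.999,3.44,0.802,1.52
F,18.998,3.98,0.557,1.47
Si,28.085,1.90,5.38,2.10
P,30.974,2.19,3.63,1.80
S,32.06,2.58,2.90,1.80
Cl,35.45,3.16,2.18,1.75
Se,78.971,2.55,3.77,1.90
Br,79.904,2.96,3.05,1.85
I,126.904,2.66,5.35,1.98
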