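# Absorption coefficients (per mm) of the principal near-infrared tissue
# chromophores, compiled from standard literature tabulations:
# hb / hbo2: whole blood (150 g Hb per litre, 64500 g/mol) fully deoxygenated /
#            fully oxygenated, from molar extinction compilations;
# water: pure water; fat: pure soft fat; melanin: cutaneous melanosome
#            power-law approximation mua ~ 51.9 * (lambda/500 nm)^-3.48.
# Linear interpolation is valid inside the tabulated range only.
wavelength_nm,hb,hbo2,water,fat,melanin
660,1.7286,0.1714,0.00040,0.00090,19.75
680,1.2899,0.1553,0.00045,0.00080,17.80
700,0.9610,0.1553,0.00060,0.00070,16.09
730,0.5903,0.2089,0.00160,0.00110,13.91
760,0.8297,0.3139,0.00266,0.00120,12.09
780,0.5758,0.3803,0.00236,0.00100,11.04
800,0.4082,0.4371,0.00220,0.00090,10.12
820,0.3712,0.4907,0.00262,0.00100,9.28
850,0.3701,0.5667,0.00430,0.00110,8.19
880,0.3889,0.6181,0.00561,0.00180,7.26
900,0.4082,0.6417,0.00679,0.00300,6.71
920,0.3969,0.6696,0.01300,0.01000,6.22
950,0.3696,0.6449,0.02620,0.00500,5.56
975,0.3321,0.6053,0.04500,0.00450,5.08
1000,0.2839,0.5624,0.03600,0.00500,4.65
1030,0.2625,0.5357,0.02600,0.00600,4.20
1064,0.2357,0.5089,0.01500,0.00500,3.75
1100,0.2143,0.4714,0.01830,0.00700,3.34
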