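element,monoisotopic_mass,isotope_shifts,isotope_abundances
H,1.00782503207,0;1,0.999885;0.000115
C,12.0,0;1,0.9893;0.0107
N,14.0030740048,0;1,0.99636;0.00364
O,15.9949146196,0;1;2,0.99757;0.00038;0.00205
F,18.99840322,0,1.0
Na,22.9897692809,0,1.0
Mg,23.9850417,0;1;2,0.7899;0.1000;0.1101
Si,27.9769265325,0;1;2,0.92223;0.04685;0.03092
P,30.97376163,0,1.0
S,31.97207100,0;1;2;4,0.9499;0.0075;0.0425;0.0001
Cl,34.96885268,0;2,0.7576;0.2424
K,38.96370668,0;1;2,0.932581;0.000117;0.067302
Ca,39.96259098,0;2;3;4;6;8,0.96941;0.00647;0.00135;0.02086;0.00004;0.00187
Zn,63.9291422,0;2;3;4;6,0.4917;0.2773;0.0404;0.1845;0.0061
Br,78.9183371,0;2,0.5069;0.4931
I,126.904473,0,1.0
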