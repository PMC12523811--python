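# Stable-isotope masses (Da) and natural abundances, NIST values; frozen for reproducibility.
element,mass_number,mass_da,abundance
H,1,1.007825032,0.999885
H,2,2.014101778,0.000115
C,12,12.000000000,0.9893
C,13,13.003354838,0.0107
N,14,14.003074005,0.99636
N,15,15.000108898,0.00364
O,16,15.994914620,0.99757
O,17,16.999131700,0.00038
O,18,17.999161000,0.00205
F,19,18.998403220,1
Na,23,22.989769281,1
Si,28,27.976926532,0.92223
Si,29,28.976494700,0.04685
Si,30,29.973770170,0.03092
P,31,30.973761630,1
S,32,31.972071000,0.9499
S,33,32.971458760,0.0075
S,34,33.967866900,0.0425
S,36,35.967080760,0.0001
Cl,35,34.968852680,0.7576
Cl,37,36.965902590,0.2424
K,39,38.963706680,0.932581
K,40,39.963998480,0.000117
K,41,40.961825760,0.067302
Br,79,78.918337100,0.5069
Br,81,80.916290600,0.4931
I,127,126.904473000,1
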