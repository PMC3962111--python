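element,polarizability
H,0.667
B,3.03
C,1.76
N,1.10
O,0.802
F,0.557
Si,5.38
P,3.63
S,2.90
Cl,2.18
As,4.31
Se,3.77
Br,3.05
Sn,7.70
I,5.35
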