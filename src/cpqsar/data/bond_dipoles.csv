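element_a,element_b,order,dipole
C,C,1,0.0
C,C,1.5,0.0
C,C,2,0.0
C,C,3,0.0
C,N,1,0.22
C,N,1.5,0.22
C,N,2,0.90
C,N,3,3.50
C,O,1,0.74
C,O,1.5,0.74
C,O,2,2.30
C,S,1,0.90
C,S,1.5,0.90
C,S,2,2.00
C,F,1,1.41
C,Cl,1,1.46
C,Br,1,1.38
C,I,1,1.19
C,P,1,0.80
N,N,1,0.0
N,N,1.5,0.0
N,N,2,0.0
N,O,1,0.30
N,O,1.5,0.30
N,O,2,2.00
O,O,1,0.0
O,S,1,0.70
O,S,2,2.80
O,P,1,1.00
O,P,2,2.70
S,S,1,0.0
S,P,1,0.80
S,P,2,2.90
N,S,1,0.50
N,P,1,0.60
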