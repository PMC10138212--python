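amino_acid,value
A,7.0
C,4.8
D,13.0
E,12.5
F,5.0
G,7.9
H,8.4
I,4.9
K,10.1
L,4.9
M,5.3
N,10.0
P,6.6
Q,8.6
R,9.1
S,7.5
T,6.6
V,5.6
W,5.2
Y,5.4
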