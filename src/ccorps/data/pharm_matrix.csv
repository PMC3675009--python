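,A,C,D,E,F,G,H,I,K,L,M,N,P,Q,R,S,T,V,W,Y
A,0,0,3,3,1,1,5,0,3,0,0,3,0,3,3,3,2,0,2,3
C,0,0,3,3,1,1,5,0,3,0,0,3,0,3,3,3,2,0,2,3
D,3,3,0,0,4,2,4,3,4,3,3,2,3,2,4,2,3,3,5,4
E,3,3,0,0,4,2,4,3,4,3,3,2,3,2,4,2,3,3,5,4
F,1,1,4,4,0,2,4,1,4,1,1,4,1,4,4,4,3,1,1,2
G,1,1,2,2,2,0,4,1,2,1,1,2,1,2,2,2,3,1,3,4
H,5,5,4,4,4,4,0,5,2,5,5,2,5,2,2,2,3,5,3,2
I,0,0,3,3,1,1,5,0,3,0,0,3,0,3,3,3,2,0,2,3
K,3,3,4,4,4,2,2,3,0,3,3,2,3,2,0,2,3,3,3,4
L,0,0,3,3,1,1,5,0,3,0,0,3,0,3,3,3,2,0,2,3
M,0,0,3,3,1,1,5,0,3,0,0,3,0,3,3,3,2,0,2,3
N,3,3,2,2,4,2,2,3,2,3,3,0,3,0,2,0,1,3,3,2
P,0,0,3,3,1,1,5,0,3,0,0,3,0,3,3,3,2,0,2,3
Q,3,3,2,2,4,2,2,3,2,3,3,0,3,0,2,0,1,3,3,2
R,3,3,4,4,4,2,2,3,0,3,3,2,3,2,0,2,3,3,3,4
S,3,3,2,2,4,2,2,3,2,3,3,0,3,0,2,0,1,3,3,2
T,2,2,3,3,3,3,3,2,3,2,2,1,2,1,3,1,0,2,2,1
V,0,0,3,3,1,1,5,0,3,0,0,3,0,3,3,3,2,0,2,3
W,2,2,5,5,1,3,3,2,3,2,2,3,2,3,3,3,2,2,0,1
Y,3,3,4,4,2,4,2,3,4,3,3,2,3,2,4,2,1,3,1,0
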