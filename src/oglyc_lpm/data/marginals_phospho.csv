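residue,-7,-6,-5,-4,-3,-2,-1,1,2,3,4,5,6,7
A,7,6.9,6.8,6.6,6.4,6.8,6.7,5.7,6.4,6.4,6.4,6.6,6.9,6.7
C,1.4,1.4,1.3,1.2,1.2,1.3,1.3,1.2,1.4,1.2,1.3,1.3,1.3,2.5
D,4.9,4.9,4.9,5,5,5.1,6.1,5.4,5.9,5.6,5.2,5.3,5.1,5.1
E,7.3,7.3,7,7.2,6.8,6.6,6,6.6,9.5,8.5,7.8,7.6,7.8,7.5
F,2.6,2.6,2.8,2.6,2.4,2.5,2.8,3.1,2.3,2.5,2.6,2.7,2.7,2.7
G,6.9,6.7,6.6,7.1,6.8,6.7,8.1,7.6,6.9,7.1,6.5,6.6,6.6,6.5
H,2.2,2.2,3.3,2.2,2.5,2.1,3.7,2,2,2.1,2.1,2.3,2.2,2.3
I,3.6,3.7,3.6,3.5,3.4,4.1,3.9,3.6,3.5,3.5,3.8,3.5,3.6,3.5
K,7.4,7.3,7,7.3,7.2,6.1,6,4.5,6,7.6,6.8,7.3,7.5,7.2
L,7.9,8.3,8.8,7.7,8,8,9.1,9.1,7.9,7.8,8.7,7.9,8,8.1
M,2.1,1.8,1.8,1.8,1.8,1.9,1.7,1.8,1.7,1.8,1.8,1.8,1.8,1.8
N,3.4,3.4,3.4,3.5,3.3,3.8,3.8,2.6,3.3,3.4,3.3,3.3,3.3,3.4
P,7.1,7,7,6.9,6.7,7.9,7.3,15.5,8,7.3,8.1,7.6,7.4,7
Q,4.5,4.4,4.3,4.8,4.1,4.4,3.8,4.6,3.9,4.3,4.2,4.3,4.4,4.3
R,7.4,7.5,7.7,7.3,11,7.3,6.8,5.1,6.1,6.8,6.4,6.9,7,7
S,10.6,10.7,10.3,11.7,10.9,11.7,9.8,9.2,11.6,11.1,11.3,10.6,10.8,10.5
T,5.7,5.5,5.3,5.4,5,5.7,4.4,4.1,5.9,5.1,5.7,5.5,5.6,5.5
V,5.2,5.2,5.2,5.1,4.8,5.4,5.5,5.3,5.2,5,5.3,5,5.3,5.1
W,0.8,0.7,0.7,0.7,0.6,0.6,0.6,0.8,0.5,0.7,0.7,0.7,0.7,0.8
Y,2.2,2.2,2.2,2.1,2,2.1,2.3,2.1,2,2.1,2.1,3.2,2.1,2.5
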