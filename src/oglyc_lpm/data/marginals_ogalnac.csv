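residue,-8,-7,-6,-5,-4,-3,-2,-1,1,2,3,4,5,6,7,8
A,7.7,7.2,7,7.2,6.6,7,9.1,8.5,7.7,10.2,7.9,6.8,8,8.2,7.9,7.8
C,0.9,0.8,0.9,0.4,0.8,0.4,0.4,0.1,0.9,0.1,0.3,0.4,0.7,0.6,0.7,1.4
D,4.3,4.5,4.1,3.8,4.1,3.4,4.2,1.3,3.9,4,4.3,3.7,5.2,4.6,4.6,5
E,6.4,6.2,6.6,6.8,6.4,8.3,6.6,4.4,7,6.2,5.2,7,7.8,6.6,7.1,8
F,2.4,2.4,2.3,2.2,2.3,2.4,2.7,2.8,1.6,2,2.7,2,2.3,2.3,2,2.2
G,6.9,6.7,6.9,6.8,6.2,5.2,7.6,5.3,5.6,7.2,6,6.8,6.1,7.6,7.8,6.8
H,3.6,3.8,2.9,4.3,4.5,3.6,3.6,4.5,3.8,4,2.8,3.5,3.5,3.2,3.4,3
I,2.9,3.2,2.7,3,3.6,3.4,3,3.2,2.4,2.7,2.3,2.7,3.2,2.1,2,2.3
K,5.7,5.4,5.7,5.8,5.1,5.6,5.5,3.3,4.6,5.6,3.6,6,5.3,5.6,6.6,7
L,6.8,7.1,6.7,7.2,6.8,8,7.1,5.6,7.5,7.1,6.1,6.7,7.2,7.7,7.1,7
M,1.7,1.3,1,0.8,0.8,1,1.1,0.9,0.7,1,0.9,1,1.1,1,1.1,1.1
N,2.1,2,2.5,2.4,2.1,2,1.2,1.7,1.7,2.6,2.1,2,2.2,2.2,2.3,2.6
P,8.3,9.6,9.4,10.2,9.4,11,11.5,15.8,11.6,12.2,17.8,12.3,9.7,10.6,8.9,8.2
Q,4.7,4.3,4.4,4.4,4.7,4.2,4.5,3.9,4.9,3.9,4.2,3.9,3.6,4,4.9,4.2
R,7.5,6.5,7.5,7.2,7.5,6.8,6.2,5.1,5.9,5.8,4.7,6.5,6.9,7.5,6.7,6.8
S,9.4,10.6,11.5,10.1,11.8,10.3,9,10.3,10.4,11.3,10.8,10.3,9.6,10.1,10.5,9.1
T,11.5,10.8,10.6,10.2,10.1,8.3,8,11.2,12,6.8,10.9,10.2,9.5,9.7,10,10.4
V,5.2,5.8,5.4,5.2,5.5,6.7,6,9.7,6.2,5.1,5.4,6.1,6,4.5,4.9,4.8
W,1,0.6,0.5,0.8,0.5,0.9,0.8,0.5,0.6,0.7,0.5,1,0.6,0.5,0.5,1.3
Y,1.3,1.4,1.2,1.4,1.5,1.6,1.8,1.7,1.2,1.5,1.7,1.4,1.4,1.5,1.3,1.3
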