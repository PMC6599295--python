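residue,-8,-7,-6,-5,-4,-3,-2,-1,1,2,3,4,5,6,7,8
A,9.1,12.7,7.1,12.1,11.5,8.8,11.8,10.3,9.1,17.4,12.1,8.5,10.3,10.6,7.4,7.1
C,0.6,1.5,0.6,0.6,0,0.9,0.3,0.6,0.3,0.3,0.6,0,0.6,0.3,0.3,0.6
D,4.4,2.7,2.7,3.8,4.1,1.5,2.4,2.7,2.9,3.5,2.1,2.4,3.2,2.4,3.8,2.4
E,4.1,6.2,5.3,5,4.1,3.5,2.1,1.2,5.3,2.9,2.7,3.8,1.8,3.8,2.9,4.1
F,1.5,1.8,2.9,1.5,2.4,2.4,1.8,1.8,2.4,1.2,1.8,1.5,2.7,2.4,1.2,1.8
G,8.5,6.2,5.9,5.9,5.3,6.8,6.8,5.6,9.4,8.5,7.1,9.1,5.6,6.5,8.8,5.9
H,3.2,0.9,2.1,0.6,3.5,2.7,1.8,1.5,1.5,2.7,1.5,1.2,2.1,3.2,1.5,3.2
I,4.4,4.7,3.2,4.1,3.5,4.4,2.9,4.4,2.9,2.1,3.5,3.2,5.9,3.8,1.8,2.9
K,7.1,6.5,5.3,8.2,7.1,3.8,7.1,3.8,4.4,1.2,2.4,5,7.4,5.9,7.4,5.9
L,7.4,5.6,6.5,10,5.9,5.6,7.1,5,5.6,4.1,7.7,5.3,7.7,6.2,5.9,6.8
M,1.2,1.5,1.8,1.5,2.1,0.3,1.2,0.9,0.6,1.2,0.3,1.8,2.4,0.9,1.5,1.2
N,2.9,1.8,3.5,0.9,1.5,2.1,1.8,0.3,1.5,2.1,3.8,1.8,1.2,2.1,1.8,2.4
P,6.2,8.2,8.5,6.5,7.7,17.9,19.4,6.8,2.7,8.8,9.1,6.5,7.9,11.8,7.7,8.8
Q,4.7,2.4,5.6,3.2,4.7,2.7,5.6,2.7,9.1,5.6,7.9,2.7,3.8,5.6,6.2,6.2
R,4.4,6.5,6.8,9.7,8.2,4.4,5.3,2.9,4.7,2.7,5,4.7,7.1,7.4,7.1,5.3
S,14.4,13.2,14.7,10,12.9,6.8,8.8,12.1,16.5,19.4,14.7,19.1,8.5,11.8,13.2,15
T,6.8,8.8,9.7,8.8,8.2,8.5,4.7,13.8,13.8,8.8,8.8,13.5,10,7.1,11.8,10
V,5.6,5,5,4.1,4.4,13.8,8.2,20,5.3,6.8,6.8,7.9,8.8,4.4,7.4,7.1
W,0.6,0.9,1.2,0.3,0.3,0.3,0,0,0,0,0.3,0,0,0,0.9,0.6
Y,2.9,3.2,1.8,3.2,2.7,2.9,1.2,3.8,2.1,0.9,2.1,2.1,3.2,4.1,1.8,2.9
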