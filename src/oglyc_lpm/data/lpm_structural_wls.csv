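variable,beta,abs_t
intercept,-0.1309,9.71
m8N,-0.0921,4.18
p7T,-0.1431,9.24
m1D,0.1878,10.74
m8P,-0.1516,11.05
p7V,-0.1309,8.14
m1L,0.0861,7.26
m8V,-0.2180,12.08
p7Y,0.1290,6.75
m1P,0.7885,11.63
p1A,0.1778,9.83
p8H,0.1164,5.76
m1R,-0.0757,4.66
p1D,0.0915,4.67
p8K,0.0570,3.34
m3A,0.2162,14.35
p1F,0.0858,5.44
p8N,0.1003,5.51
m3C,-0.1315,6.45
p1S,0.0835,5.33
p8Q,0.1493,8.53
m3L,-0.1139,9.49
p1T,0.1673,10.15
pos,0.2821,15.95
m3N,-0.2245,5.86
p1V,0.0669,4.97
ASA_zero,0.8057,12.02
m3T,-0.0881,5.14
p2A,0.0590,2.92
II,0.1649,6.95
m4E,0.1296,5.3
p2H,0.3143,11.32
II´,-0.2828,7.58
m4F,-0.0848,5.56
p2P,0.2652,18.99
Helix,0.1610,14.88
m4N,0.1419,7.3
p2Q,-0.1532,7.89
Beta Bridges,0.6077,6.53
m4R,0.1410,7.04
p2Y,-0.2434,8.12
Beta Hairpin,0.7884,22.3
m4V,-0.0545,4.18
p3N,-0.1615,7.69
Beta Hairpin Strand,-0.1044,9.83
m5D,0.2521,13.74
p3W,-0.1086,3.41
Phi angle,-0.0004,5.31
m5F,-0.1257,6
p4A,0.1629,9.62
m5G,0.0700,3.21
p4E,0.1757,12.53
m5I,-0.0981,4.85
p4P,0.1921,13.35
m5Y,-0.1468,6.9
p5C,-0.1957,9.63
m6E,0.0954,7.08
p5E,0.1718,7.98
m6H,-0.1245,4.73
p5H,0.1938,7.88
m6V,0.1528,9.82
p5I,-0.0760,4.33
m6W,0.1166,4.9
p5Q,0.1060,4.93
m6Y,-0.1265,6.31
p5T,0.0722,4.61
m7A,0.1576,10.18
p5Y,-0.1876,7.45
m7E,-0.1132,6.87
p6F,-0.1155,5.43
m7G,-0.0685,4.89
p6G,-0.1696,10.07
m7H,0.2427,11.33
p6M,0.3118,9.57
m7I,0.1222,7.67
p6N,-0.1209,6.67
m7K,0.1538,8.77
p6Q,-0.2641,12.26
m7S,0.0826,4.44
p7A,0.1752,7.04
m8G,0.1032,6.68
p7C,-0.1281,5.86
m8L,-0.1541,10.43
p7E,-0.1161,7.36
m8M,-0.1234,5.34
p7G,-0.0951,5.81
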