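variable,beta,white_abs_t
intercept,-0.1177,5.17
m8N,-0.0842,3.18
p7T,-0.1371,6.97
m1D,0.1827,5.30
m8P,-0.1387,6.82
p7V,-0.1173,4.68
m1L,0.0930,3.71
m8V,-0.2103,7.60
p7Y,0.1188,4.05
m1P,0.7844,13.86
p1A,0.1754,5.59
p8H,0.1194,2.51
m1R,-0.0619,2.34
p1D,0.0984,2.65
p8K,0.0484,1.52
m3A,0.2046,8.22
p1F,0.0831,2.43
p8N,0.1052,3.22
m3C,-0.1245,4.37
p1S,0.0884,3.27
p8Q,0.1466,4.52
m3L,-0.1099,6.18
p1T,0.1567,4.59
pos,0.2509,8.51
m3N,-0.2151,3.23
p1V,0.0623,3.34
ASA_zero,0.7952,9.89
m3T,-0.0743,2.90
p2A,0.0697,1.33
II,0.1387,3.12
m4E,0.1109,2.61
p2H,0.2885,4.65
II´,-0.2684,4.04
m4F,-0.0881,3.43
p2P,0.2730,9.84
Helix,0.1508,7.66
m4N,0.1405,3.27
p2Q,-0.1379,4.70
Beta Bridges,0.6330,9.35
m4R,0.1408,3.71
p2Y,-0.1906,3.98
Beta Hairpin,0.8016,13.87
m4V,-0.0560,2.91
p3N,-0.1483,5.13
Beta Hairpin Strand,-0.0916,5.34
m5D,0.2333,6.89
p3W,-0.1152,3.37
Phi angle,-0.0003,3.04
m5F,-0.0941,2.85
p4A,0.1650,4.77
m5G,0.0560,1.75
p4E,0.1711,6.75
m5I,-0.0872,2.61
p4P,0.1946,8.26
m5Y,-0.1326,4.60
p5C,-0.1742,5.23
m6E,0.0916,3.22
p5E,0.1512,4.93
m6H,-0.1270,5.34
p5H,0.2173,4.08
m6V,0.1567,3.99
p5I,-0.0783,3.52
m6W,0.1063,2.81
p5Q,0.1209,3.16
m6Y,-0.1267,4.11
p5T,0.0651,2.79
m7A,0.1622,5.51
p5Y,-0.1818,4.60
m7E,-0.1072,4.70
p6F,-0.0883,1.97
m7G,-0.0703,3.42
p6G,-0.1561,5.14
m7H,0.2640,5.12
p6M,0.3066,4.87
m7I,0.1141,5.62
p6N,-0.1144,5.29
m7K,0.1366,3.55
p6Q,-0.2447,7.92
m7S,0.0859,2.72
p7A,0.1803,3.10
m8G,0.0964,4.51
p7C,-0.1207,3.99
m8L,-0.1518,5.28
p7E,-0.1148,4.67
m8M,-0.1187,4.49
p7G,-0.0945,3.50
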