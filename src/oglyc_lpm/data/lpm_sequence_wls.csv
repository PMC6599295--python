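variable,beta,abs_t
intercept,0.1379,3.27
p1S,0.2446,5.33
m1C,-0.2020,2.11
p1T,0.2268,4.48
m1F,-0.1373,1.96
p2A,0.2120,4.44
m1P,0.4708,5.44
p2D,0.2029,2.73
m1T,0.1535,3.25
p2F,-0.2292,2.43
m1V,0.1348,3.41
p2G,0.1706,3.01
m3F,-0.1950,2.92
p2L,-0.1342,2.64
m3L,-0.1367,2.65
p2S,0.2068,4.69
m3P,0.1852,4
p3Q,0.1914,3.12
m3V,0.1103,2.3
p3S,0.1041,2.29
m4C,-0.6595,4.9
p4A,0.2149,3.66
m4F,-0.2551,4.1
p4G,0.2195,3.93
m4L,-0.1180,2.28
p4S,0.1277,3.07
m4Q,-0.2802,4.52
p4T,0.1867,3.81
m4V,-0.2253,4.37
p5A,0.0934,1.77
m4Y,-0.2037,3.03
p5C,-0.3927,4.63
m5A,0.1224,2.28
p5L,-0.1029,2.04
m5C,-0.2515,2.6
p5N,-0.3141,3.6
m5H,-0.3195,3.45
p5W,-0.7183,3.72
m5N,-0.2492,2.9
p6C,-0.3787,4.2
m5R,0.1419,2.57
p7A,0.1763,2.71
m5W,-0.2752,1.96
p7C,-0.2791,3.06
m5Y,-0.1507,2.15
p7G,0.1366,2.5
m6R,0.1362,2.31
p7K,0.1578,2.73
m6Y,-0.2011,2.49
p7T,0.1968,3.98
m7L,-0.0910,1.86
p8F,-0.1867,2.86
m7M,-0.2490,2.83
p8S,0.1625,3.5
m7R,0.2907,4.38
pos,0.2406,4.35
m8A,0.1563,2.7
m8K,0.1726,2.9
p1A,0.2092,3.78
p1G,0.1706,3.23
p1K,0.2524,3.37
p1P,0.4464,3.26
p1Q,0.1728,3.05
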