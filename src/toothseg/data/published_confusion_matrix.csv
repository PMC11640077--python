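Tooth Number,Background,11,12,13,14,15,16,17,18,21,22,23,24,25,26,27,28,31,32,33,34,35,36,37,38,41,42,43,44,45,46,47,48
Background,6913832,2551,2133,2584,2623,1747,3597,2730,1509,2301,1732,1945,2449,1575,3226,2917,1740,1693,2016,2054,2099,1572,2758,3966,1759,1737,1520,2245,1693,2021,2861,2839,2456
11,1388,36448,197,0,0,0,0,0,0,20,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,2,4,0,0,0,0,0,0
12,1139,86,29074,159,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,3,0,0,0,0,0
13,1802,0,91,35299,1658,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
14,1370,0,0,351,27929,1647,4,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,4,0,0,0
15,1143,0,0,0,366,27775,543,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0
16,1795,0,0,0,0,97,39779,176,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
17,2031,0,0,0,0,0,1261,41841,388,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
18,1847,0,0,0,0,0,0,224,23861,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
21,1573,44,0,0,0,0,0,0,0,36717,297,0,0,0,0,0,0,8,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
22,1140,0,0,0,0,0,0,0,0,95,27763,1286,8,0,0,0,0,0,3,2,0,0,0,0,0,0,0,0,0,0,0,0,0
23,1681,0,0,0,0,0,0,0,0,0,32,36138,2176,0,0,0,0,0,0,0,2,0,0,0,0,0,0,0,0,0,0,0,0
24,1600,0,0,0,0,0,0,0,0,0,0,164,29274,1628,2,0,0,0,0,0,0,7,0,0,0,0,0,0,0,0,0,0,0
25,1517,0,0,0,0,0,0,0,0,0,0,0,919,25902,380,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
26,2452,0,0,0,0,0,0,0,0,0,0,0,0,623,40779,1441,0,0,0,0,0,0,0,2,0,0,0,0,0,0,0,0,0
27,2062,0,0,0,0,0,0,0,0,0,0,0,0,0,906,39462,1410,0,0,0,0,0,0,3,0,0,0,0,0,0,0,0,0
28,1251,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1472,21569,0,0,0,0,0,0,0,19,0,0,0,0,0,0,0,0
31,860,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,20519,19,0,0,0,0,0,0,43,0,0,0,0,0,0,0
32,690,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,34,23705,28,0,0,0,0,0,0,0,0,0,0,0,0,0
33,1358,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,9,36588,178,0,0,0,0,0,0,0,0,0,0,0,0
34,788,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,36,29601,818,5,0,0,0,0,0,0,0,0,0,0
35,825,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,32,30614,488,0,0,0,0,0,0,0,0,0,0
36,1772,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,85,44058,1241,18,0,0,0,0,0,0,0,0
37,1447,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1397,51500,1494,0,0,0,0,0,0,0,0
38,1389,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,2,0,0,0,0,0,0,1237,33372,0,0,0,0,0,0,0,0
41,785,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,21,0,0,0,0,0,0,0,20402,31,0,0,0,0,0,0
42,978,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,46,23930,50,0,0,0,0,0
43,1173,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,20,36286,343,0,0,0,0
44,1377,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,62,31120,665,0,0,0
45,1057,0,0,0,6,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,29,30161,521,0,0
46,1349,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,55,41272,1195,8
47,1471,0,0,0,0,0,2,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,54,55358,1401
48,1356,0,0,0,0,0,0,7,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,5,35524
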