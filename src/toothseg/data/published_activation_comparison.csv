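Tooth Number,Sigmoid F1-Score,Sigmoid mIoU,SoftMax F1-Score,SoftMax mIoU
11,94.59,89.74,94.42,89.42
12,93.97,88.62,93.70,88.14
13,92.61,86.23,88.61,79.55
14,89.63,81.21,82.71,70.52
15,92.30,85.70,89.60,81.16
16,91.65,84.58,91.28,83.96
17,92.78,86.54,90.58,82.79
18,92.08,85.32,89.71,81.35
21,94.52,89.62,94.61,89.77
22,92.38,85.85,92.71,86.41
23,92.49,86.04,89.90,81.66
24,88.62,79.57,84.99,73.90
25,89.59,81.14,88.28,79.02
26,90.22,82.19,90.98,83.45
27,88.34,79.12,88.96,80.11
28,88.19,78.88,87.00,77.00
31,93.95,88.59,92.77,87.28
32,94.63,89.82,93.92,89.34
33,95.33,91.07,94.99,90.46
34,94.17,88.99,93.03,86.97
35,94.61,89.78,93.65,88.07
36,91.98,85.15,89.46,80.93
37,90.79,83.13,88.67,79.64
38,91.72,84.72,91.18,83.79
41,94.14,88.93,93.31,87.46
42,94.61,89.77,94.20,89.05
43,95.28,91.00,94.66,89.86
44,94.69,89.92,94.07,88.81
45,94.21,89.05,93.94,88.58
46,93.63,88.02,93.31,88.24
47,94.17,88.99,94.52,90.42
48,93.13,87.15,94.45,89.48
Average,92.66,86.39,91.51,84.58
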