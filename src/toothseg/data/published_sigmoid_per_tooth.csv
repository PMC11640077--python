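Tooth Number,F1-Score,mIoU,Precision,Recall,Acc
11,94.59,89.74,94.52,94.65,99.94
12,93.97,88.62,94.32,93.62,99.95
13,92.61,86.23,92.32,92.89,99.92
14,89.63,81.21,90.14,89.12,99.90
15,92.30,85.70,92.56,92.04,99.93
16,91.65,84.58,89.62,93.77,99.90
17,92.78,86.54,94.35,91.26,99.92
18,92.08,85.32,93.74,90.47,99.94
21,94.52,89.62,94.96,94.09,99.94
22,92.38,85.85,94.14,90.69,99.94
23,92.49,86.04,92.46,92.52,99.92
24,88.62,79.57,87.24,90.05,99.89
25,89.59,81.14,91.66,87.60,99.91
26,90.22,82.19,91.83,88.67,99.89
27,88.34,79.12,88.17,88.52,99.87
28,88.19,78.88,89.10,87.30,99.92
31,93.95,88.59,93.80,94.09,99.96
32,94.63,89.82,93.73,95.56,99.96
33,95.33,91.07,95.81,94.84,99.95
34,94.17,88.99,94.25,94.10,99.95
35,94.61,89.78,94.20,95.03,99.95
36,91.98,85.15,91.84,92.12,99.90
37,90.79,83.13,90.08,91.51,99.87
38,91.72,84.72,92.09,91.36,99.92
41,94.14,88.93,93.75,94.53,99.96
42,94.61,89.77,95.23,93.99,99.96
43,95.28,91.00,95.27,95.29,99.95
44,94.69,89.92,95.40,93.99,99.95
45,94.21,89.05,94.03,94.38,99.95
46,93.63,88.02,94.31,92.96,99.92
47,94.17,88.99,94.59,93.76,99.91
48,93.13,87.15,91.38,94.95,99.93
Average,92.66,86.39,92.84,92.49,99.93
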