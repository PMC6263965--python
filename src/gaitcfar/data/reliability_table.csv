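subject,gender,tam,lopez_meyer,pm,sttta,mariani
1,male,91.49,92.52,89.85,88.91,86.61
2,male,90.89,92.49,92.31,91.23,89.63
3,male,86.33,89.43,86.35,92.42,91.07
4,male,90.26,91.15,87.96,85.56,88.89
5,male,88.68,90.81,91.23,89.98,89.62
6,male,90.96,85.66,90.96,91.32,90.06
7,male,92.01,91.57,85.65,92.04,90.65
8,male,89.46,91.81,92.12,87.99,86.30
9,male,89.17,86.55,88.64,88.27,87.96
10,male,85.32,91.22,92.31,84.42,87.34
11,male,89.27,94.93,84.69,89.81,86.58
12,male,88.38,91.96,88.96,88.84,89.39
13,female,86.22,89.04,92.35,92.29,90.25
14,female,87.61,85.78,91.20,91.70,89.11
15,female,90.53,89.32,88.99,90.52,85.98
16,female,96.41,88.95,89.62,90.59,87.19
17,female,90.12,89.81,86.34,91.23,88.67
18,female,92.11,89.61,91.37,93.12,90.96
19,female,94.22,91.27,89.91,90.06,91.41
20,female,91.75,86.33,87.65,88.93,89.47
21,female,91.91,86.12,90.03,87.32,88.58
22,female,91.49,92.52,89.85,93.05,90.05
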