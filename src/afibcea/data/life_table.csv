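# Synthetic general-population life table (Gompertz-shaped annual death
# probabilities, unisex, calibration anchor q(65)=0.013 doubling ~7.2 y).
# Scaled at run time by config.mortality_multiplier.
age,annual_death_probability
60,0.00803
61,0.00884
62,0.00974
63,0.01072
64,0.01181
65,0.01300
66,0.01431
67,0.01576
68,0.01735
69,0.01911
70,0.02104
71,0.02317
72,0.02551
73,0.02809
74,0.03093
75,0.03405
76,0.03750
77,0.04129
78,0.04546
79,0.05006
80,0.05512
81,0.06069
82,0.06682
83,0.07358
84,0.08102
85,0.08921
86,0.09822
87,0.10815
88,0.11909
89,0.13112
90,0.14438
91,0.15898
92,0.17505
93,0.19274
94,0.21223
95,0.23368
96,0.25730
97,0.28331
98,0.31195
99,0.34349
100,0.37821
101,0.41644
102,0.45854
103,0.50489
104,0.55593
105,0.61213
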