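# Synthetic stand-in for the Thai national period life table (both sexes).
# Gompertz-Makeham hazard h(x) = 0.002 + 3.34e-5*exp(0.090*x), calibrated to
# Thai demography (annual q(65) ~ 0.0135, e65 ~ 19.5 y), tabulated as 5-year
# grouped death probabilities applied per single year of age, the form in
# which abridged national mortality schedules are published.
age,qx
60,0.053161
61,0.053161
62,0.053161
63,0.053161
64,0.053161
65,0.076873
66,0.076873
67,0.076873
68,0.076873
69,0.076873
70,0.112869
71,0.112869
72,0.112869
73,0.112869
74,0.112869
75,0.166518
76,0.166518
77,0.166518
78,0.166518
79,0.166518
80,0.244196
81,0.244196
82,0.244196
83,0.244196
84,0.244196
85,0.351701
86,0.351701
87,0.351701
88,0.351701
89,0.351701
90,0.490348
91,0.490348
92,0.490348
93,0.490348
94,0.490348
95,0.650553
96,0.650553
97,0.650553
98,0.650553
99,0.650553
100,0.806648
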