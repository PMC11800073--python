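# synthetic 120 kVp x-ray source spectrum
# Kramers-law bremsstrahlung filtered by 0.8 mm Be, 1.0 mm Al, 0.11 mm Cu
# columns: energy_keV  relative_photon_fluence
12.0 1.932173e-10
13.0 1.411405e-08
14.0 3.241090e-07
15.0 3.356776e-06
16.0 1.981492e-05
17.0 7.794156e-05
18.0 2.273723e-04
19.0 5.302226e-04
20.0 1.042787e-03
21.0 1.798331e-03
22.0 2.798873e-03
23.0 4.017062e-03
24.0 5.404600e-03
25.0 6.902686e-03
26.0 8.451263e-03
27.0 9.995580e-03
28.0 1.148993e-02
29.0 1.289905e-02
30.0 1.419795e-02
31.0 1.537080e-02
32.0 1.640939e-02
33.0 1.731151e-02
34.0 1.807947e-02
35.0 1.871875e-02
36.0 1.923695e-02
37.0 1.964293e-02
38.0 1.994619e-02
39.0 2.015640e-02
40.0 2.028303e-02
41.0 2.033518e-02
42.0 2.032141e-02
43.0 2.024965e-02
44.0 2.012720e-02
45.0 1.996069e-02
46.0 1.975611e-02
47.0 1.951884e-02
48.0 1.925371e-02
49.0 1.896498e-02
50.0 1.865647e-02
51.0 1.833154e-02
52.0 1.799315e-02
53.0 1.764390e-02
54.0 1.728610e-02
55.0 1.692174e-02
56.0 1.655256e-02
57.0 1.618011e-02
58.0 1.580570e-02
59.0 1.543049e-02
60.0 1.505546e-02
61.0 1.468148e-02
62.0 1.430928e-02
63.0 1.393950e-02
64.0 1.357266e-02
65.0 1.320923e-02
66.0 1.284959e-02
67.0 1.249404e-02
68.0 1.214287e-02
69.0 1.179628e-02
70.0 1.145445e-02
71.0 1.111751e-02
72.0 1.078556e-02
73.0 1.045868e-02
74.0 1.013692e-02
75.0 9.820314e-03
76.0 9.508866e-03
77.0 9.202574e-03
78.0 8.901419e-03
79.0 8.605371e-03
80.0 8.314390e-03
81.0 8.028427e-03
82.0 7.747426e-03
83.0 7.471325e-03
84.0 7.200058e-03
85.0 6.933553e-03
86.0 6.671736e-03
87.0 6.414530e-03
88.0 6.161856e-03
89.0 5.913633e-03
90.0 5.669780e-03
91.0 5.430214e-03
92.0 5.194853e-03
93.0 4.963613e-03
94.0 4.736413e-03
95.0 4.513170e-03
96.0 4.293802e-03
97.0 4.078230e-03
98.0 3.866372e-03
99.0 3.658151e-03
100.0 3.453489e-03
101.0 3.252309e-03
102.0 3.054537e-03
103.0 2.860098e-03
104.0 2.668920e-03
105.0 2.480932e-03
106.0 2.296065e-03
107.0 2.114250e-03
108.0 1.935420e-03
109.0 1.759511e-03
110.0 1.586458e-03
111.0 1.416199e-03
112.0 1.248674e-03
113.0 1.083822e-03
114.0 9.215847e-04
115.0 7.619065e-04
116.0 6.047314e-04
117.0 4.500053e-04
118.0 2.976755e-04
119.0 1.476905e-04
120.0 0.000000e+00
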