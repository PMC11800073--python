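# synthetic mass attenuation table for cortical_bone
# two-term parametric fit (photoelectric + Klein-Nishina) to anchor values
# density_g_cm3: 1.92
# columns: energy_keV  mu_over_rho_cm2_g
10.0 3.106608e+01
11.0 2.338976e+01
12.0 1.806144e+01
13.0 1.424777e+01
14.0 1.144656e+01
15.0 9.342879e+00
16.0 7.732408e+00
17.0 6.478637e+00
18.0 5.487998e+00
19.0 4.694897e+00
20.0 4.052424e+00
21.0 3.526427e+00
22.0 3.091640e+00
23.0 2.729098e+00
24.0 2.424380e+00
25.0 2.166384e+00
26.0 1.946473e+00
27.0 1.757856e+00
28.0 1.595146e+00
29.0 1.454031e+00
30.0 1.331032e+00
31.0 1.223323e+00
32.0 1.128590e+00
33.0 1.044927e+00
34.0 9.707558e-01
35.0 9.047588e-01
36.0 8.458331e-01
37.0 7.930496e-01
38.0 7.456220e-01
39.0 7.028819e-01
40.0 6.642583e-01
41.0 6.292622e-01
42.0 5.974724e-01
43.0 5.685253e-01
44.0 5.421056e-01
45.0 5.179393e-01
46.0 4.957870e-01
47.0 4.754396e-01
48.0 4.567133e-01
49.0 4.394465e-01
50.0 4.234965e-01
51.0 4.087371e-01
52.0 3.950564e-01
53.0 3.823548e-01
54.0 3.705438e-01
55.0 3.595441e-01
56.0 3.492849e-01
57.0 3.397027e-01
58.0 3.307404e-01
59.0 3.223466e-01
60.0 3.144750e-01
61.0 3.070838e-01
62.0 3.001352e-01
63.0 2.935947e-01
64.0 2.874313e-01
65.0 2.816166e-01
66.0 2.761248e-01
67.0 2.709324e-01
68.0 2.660179e-01
69.0 2.613617e-01
70.0 2.569458e-01
71.0 2.527537e-01
72.0 2.487703e-01
73.0 2.449816e-01
74.0 2.413749e-01
75.0 2.379384e-01
76.0 2.346612e-01
77.0 2.315332e-01
78.0 2.285451e-01
79.0 2.256884e-01
80.0 2.229552e-01
81.0 2.203380e-01
82.0 2.178300e-01
83.0 2.154248e-01
84.0 2.131166e-01
85.0 2.108998e-01
86.0 2.087693e-01
87.0 2.067203e-01
88.0 2.047485e-01
89.0 2.028495e-01
90.0 2.010196e-01
91.0 1.992551e-01
92.0 1.975526e-01
93.0 1.959090e-01
94.0 1.943211e-01
95.0 1.927863e-01
96.0 1.913019e-01
97.0 1.898654e-01
98.0 1.884746e-01
99.0 1.871271e-01
100.0 1.858211e-01
101.0 1.845545e-01
102.0 1.833255e-01
103.0 1.821324e-01
104.0 1.809736e-01
105.0 1.798475e-01
106.0 1.787527e-01
107.0 1.776879e-01
108.0 1.766517e-01
109.0 1.756429e-01
110.0 1.746604e-01
111.0 1.737031e-01
112.0 1.727698e-01
113.0 1.718598e-01
114.0 1.709719e-01
115.0 1.701053e-01
116.0 1.692592e-01
117.0 1.684328e-01
118.0 1.676253e-01
119.0 1.668360e-01
120.0 1.660641e-01
121.0 1.653092e-01
122.0 1.645704e-01
123.0 1.638473e-01
124.0 1.631392e-01
125.0 1.624456e-01
126.0 1.617661e-01
127.0 1.611001e-01
128.0 1.604471e-01
129.0 1.598067e-01
130.0 1.591784e-01
131.0 1.585619e-01
132.0 1.579568e-01
133.0 1.573627e-01
134.0 1.567792e-01
135.0 1.562059e-01
136.0 1.556427e-01
137.0 1.550891e-01
138.0 1.545448e-01
139.0 1.540095e-01
140.0 1.534831e-01
141.0 1.529651e-01
142.0 1.524554e-01
143.0 1.519537e-01
144.0 1.514598e-01
145.0 1.509734e-01
146.0 1.504944e-01
147.0 1.500224e-01
148.0 1.495574e-01
149.0 1.490991e-01
150.0 1.486473e-01
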