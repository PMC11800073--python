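# synthetic mass attenuation table for blood
# two-term parametric fit (photoelectric + Klein-Nishina) to anchor values
# density_g_cm3: 1.06
# columns: energy_keV  mu_over_rho_cm2_g
10.0 5.000508e+00
11.0 3.809694e+00
12.0 2.982922e+00
13.0 2.390988e+00
14.0 1.956033e+00
15.0 1.629229e+00
16.0 1.378898e+00
17.0 1.183876e+00
18.0 1.029657e+00
19.0 9.060694e-01
20.0 8.058413e-01
21.0 7.236773e-01
22.0 6.556601e-01
23.0 5.988495e-01
24.0 5.510093e-01
25.0 5.104184e-01
26.0 4.757375e-01
27.0 4.459137e-01
28.0 4.201117e-01
29.0 3.976628e-01
30.0 3.780279e-01
31.0 3.607684e-01
32.0 3.455256e-01
33.0 3.320041e-01
34.0 3.199588e-01
35.0 3.091857e-01
36.0 2.995135e-01
37.0 2.907983e-01
38.0 2.829179e-01
39.0 2.757688e-01
40.0 2.692624e-01
41.0 2.633227e-01
42.0 2.578845e-01
43.0 2.528912e-01
44.0 2.482941e-01
45.0 2.440504e-01
46.0 2.401231e-01
47.0 2.364797e-01
48.0 2.330916e-01
49.0 2.299337e-01
50.0 2.269839e-01
51.0 2.242226e-01
52.0 2.216323e-01
53.0 2.191976e-01
54.0 2.169046e-01
55.0 2.147411e-01
56.0 2.126961e-01
57.0 2.107596e-01
58.0 2.089227e-01
59.0 2.071775e-01
60.0 2.055167e-01
61.0 2.039338e-01
62.0 2.024229e-01
63.0 2.009786e-01
64.0 1.995961e-01
65.0 1.982709e-01
66.0 1.969989e-01
67.0 1.957766e-01
68.0 1.946005e-01
69.0 1.934676e-01
70.0 1.923749e-01
71.0 1.913201e-01
72.0 1.903005e-01
73.0 1.893142e-01
74.0 1.883590e-01
75.0 1.874330e-01
76.0 1.865347e-01
77.0 1.856623e-01
78.0 1.848144e-01
79.0 1.839897e-01
80.0 1.831868e-01
81.0 1.824046e-01
82.0 1.816421e-01
83.0 1.808981e-01
84.0 1.801719e-01
85.0 1.794623e-01
86.0 1.787688e-01
87.0 1.780904e-01
88.0 1.774264e-01
89.0 1.767763e-01
90.0 1.761393e-01
91.0 1.755149e-01
92.0 1.749026e-01
93.0 1.743017e-01
94.0 1.737118e-01
95.0 1.731325e-01
96.0 1.725633e-01
97.0 1.720038e-01
98.0 1.714536e-01
99.0 1.709125e-01
100.0 1.703799e-01
101.0 1.698556e-01
102.0 1.693394e-01
103.0 1.688308e-01
104.0 1.683297e-01
105.0 1.678358e-01
106.0 1.673487e-01
107.0 1.668684e-01
108.0 1.663946e-01
109.0 1.659270e-01
110.0 1.654655e-01
111.0 1.650099e-01
112.0 1.645600e-01
113.0 1.641155e-01
114.0 1.636765e-01
115.0 1.632426e-01
116.0 1.628138e-01
117.0 1.623900e-01
118.0 1.619708e-01
119.0 1.615564e-01
120.0 1.611464e-01
121.0 1.607409e-01
122.0 1.603396e-01
123.0 1.599425e-01
124.0 1.595495e-01
125.0 1.591604e-01
126.0 1.587753e-01
127.0 1.583939e-01
128.0 1.580162e-01
129.0 1.576421e-01
130.0 1.572715e-01
131.0 1.569044e-01
132.0 1.565407e-01
133.0 1.561802e-01
134.0 1.558230e-01
135.0 1.554689e-01
136.0 1.551180e-01
137.0 1.547700e-01
138.0 1.544250e-01
139.0 1.540830e-01
140.0 1.537438e-01
141.0 1.534074e-01
142.0 1.530737e-01
143.0 1.527427e-01
144.0 1.524144e-01
145.0 1.520887e-01
146.0 1.517655e-01
147.0 1.514448e-01
148.0 1.511266e-01
149.0 1.508108e-01
150.0 1.504973e-01
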