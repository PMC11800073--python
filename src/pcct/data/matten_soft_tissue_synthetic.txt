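# synthetic mass attenuation table for soft_tissue
# two-term parametric fit (photoelectric + Klein-Nishina) to anchor values
# density_g_cm3: 1.06
# columns: energy_keV  mu_over_rho_cm2_g
10.0 4.836019e+00
11.0 3.685978e+00
12.0 2.887508e+00
13.0 2.315829e+00
14.0 1.895751e+00
15.0 1.580119e+00
16.0 1.338341e+00
17.0 1.149977e+00
18.0 1.001018e+00
19.0 8.816417e-01
20.0 7.848245e-01
21.0 7.054527e-01
22.0 6.397433e-01
23.0 5.848567e-01
24.0 5.386334e-01
25.0 4.994112e-01
26.0 4.658968e-01
27.0 4.370732e-01
28.0 4.121338e-01
29.0 3.904329e-01
30.0 3.714496e-01
31.0 3.547606e-01
32.0 3.400195e-01
33.0 3.269408e-01
34.0 3.152879e-01
35.0 3.048638e-01
36.0 2.955031e-01
37.0 2.870667e-01
38.0 2.794368e-01
39.0 2.725132e-01
40.0 2.662104e-01
41.0 2.604552e-01
42.0 2.551844e-01
43.0 2.503434e-01
44.0 2.458851e-01
45.0 2.417684e-01
46.0 2.379574e-01
47.0 2.344206e-01
48.0 2.311306e-01
49.0 2.280631e-01
50.0 2.251967e-01
51.0 2.225124e-01
52.0 2.199934e-01
53.0 2.176248e-01
54.0 2.153933e-01
55.0 2.132869e-01
56.0 2.112951e-01
57.0 2.094082e-01
58.0 2.076176e-01
59.0 2.059157e-01
60.0 2.042955e-01
61.0 2.027506e-01
62.0 2.012753e-01
63.0 1.998646e-01
64.0 1.985135e-01
65.0 1.972180e-01
66.0 1.959740e-01
67.0 1.947781e-01
68.0 1.936269e-01
69.0 1.925175e-01
70.0 1.914472e-01
71.0 1.904134e-01
72.0 1.894139e-01
73.0 1.884465e-01
74.0 1.875093e-01
75.0 1.866005e-01
76.0 1.857184e-01
77.0 1.848616e-01
78.0 1.840284e-01
79.0 1.832178e-01
80.0 1.824284e-01
81.0 1.816590e-01
82.0 1.809087e-01
83.0 1.801765e-01
84.0 1.794614e-01
85.0 1.787626e-01
86.0 1.780793e-01
87.0 1.774108e-01
88.0 1.767563e-01
89.0 1.761152e-01
90.0 1.754870e-01
91.0 1.748709e-01
92.0 1.742666e-01
93.0 1.736735e-01
94.0 1.730910e-01
95.0 1.725189e-01
96.0 1.719566e-01
97.0 1.714038e-01
98.0 1.708601e-01
99.0 1.703251e-01
100.0 1.697985e-01
101.0 1.692800e-01
102.0 1.687694e-01
103.0 1.682662e-01
104.0 1.677703e-01
105.0 1.672815e-01
106.0 1.667994e-01
107.0 1.663238e-01
108.0 1.658546e-01
109.0 1.653915e-01
110.0 1.649343e-01
111.0 1.644829e-01
112.0 1.640370e-01
113.0 1.635966e-01
114.0 1.631614e-01
115.0 1.627313e-01
116.0 1.623061e-01
117.0 1.618858e-01
118.0 1.614701e-01
119.0 1.610590e-01
120.0 1.606523e-01
121.0 1.602499e-01
122.0 1.598518e-01
123.0 1.594577e-01
124.0 1.590676e-01
125.0 1.586815e-01
126.0 1.582991e-01
127.0 1.579204e-01
128.0 1.575454e-01
129.0 1.571739e-01
130.0 1.568059e-01
131.0 1.564413e-01
132.0 1.560800e-01
133.0 1.557219e-01
134.0 1.553671e-01
135.0 1.550153e-01
136.0 1.546665e-01
137.0 1.543208e-01
138.0 1.539780e-01
139.0 1.536380e-01
140.0 1.533008e-01
141.0 1.529665e-01
142.0 1.526348e-01
143.0 1.523057e-01
144.0 1.519793e-01
145.0 1.516554e-01
146.0 1.513341e-01
147.0 1.510152e-01
148.0 1.506987e-01
149.0 1.503847e-01
150.0 1.500729e-01
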