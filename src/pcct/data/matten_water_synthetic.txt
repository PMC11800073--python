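# synthetic mass attenuation table for water
# two-term parametric fit (photoelectric + Klein-Nishina) to anchor values
# density_g_cm3: 1.0
# columns: energy_keV  mu_over_rho_cm2_g
10.0 4.917899e+00
11.0 3.747805e+00
12.0 2.935415e+00
13.0 2.353773e+00
14.0 1.926376e+00
15.0 1.605247e+00
16.0 1.359260e+00
17.0 1.167619e+00
18.0 1.016070e+00
19.0 8.946194e-01
20.0 7.961216e-01
21.0 7.153735e-01
22.0 6.485261e-01
23.0 5.926901e-01
24.0 5.456685e-01
25.0 5.057701e-01
26.0 4.716789e-01
27.0 4.423604e-01
28.0 4.169937e-01
29.0 3.949219e-01
30.0 3.756151e-01
31.0 3.586426e-01
32.0 3.436518e-01
33.0 3.303524e-01
34.0 3.185036e-01
35.0 3.079049e-01
36.0 2.983881e-01
37.0 2.898117e-01
38.0 2.820558e-01
39.0 2.750185e-01
40.0 2.686128e-01
41.0 2.627641e-01
42.0 2.574082e-01
43.0 2.524896e-01
44.0 2.479603e-01
45.0 2.437785e-01
46.0 2.399076e-01
47.0 2.363157e-01
48.0 2.329749e-01
49.0 2.298603e-01
50.0 2.269503e-01
51.0 2.242256e-01
52.0 2.216690e-01
53.0 2.192654e-01
54.0 2.170011e-01
55.0 2.148642e-01
56.0 2.128437e-01
57.0 2.109300e-01
58.0 2.091142e-01
59.0 2.073886e-01
60.0 2.057461e-01
61.0 2.041801e-01
62.0 2.026850e-01
63.0 2.012554e-01
64.0 1.998866e-01
65.0 1.985741e-01
66.0 1.973141e-01
67.0 1.961029e-01
68.0 1.949373e-01
69.0 1.938141e-01
70.0 1.927306e-01
71.0 1.916842e-01
72.0 1.906727e-01
73.0 1.896938e-01
74.0 1.887456e-01
75.0 1.878262e-01
76.0 1.869340e-01
77.0 1.860674e-01
78.0 1.852250e-01
79.0 1.844053e-01
80.0 1.836072e-01
81.0 1.828296e-01
82.0 1.820712e-01
83.0 1.813312e-01
84.0 1.806086e-01
85.0 1.799026e-01
86.0 1.792122e-01
87.0 1.785369e-01
88.0 1.778758e-01
89.0 1.772284e-01
90.0 1.765939e-01
91.0 1.759719e-01
92.0 1.753617e-01
93.0 1.747629e-01
94.0 1.741749e-01
95.0 1.735974e-01
96.0 1.730299e-01
97.0 1.724719e-01
98.0 1.719232e-01
99.0 1.713834e-01
100.0 1.708521e-01
101.0 1.703290e-01
102.0 1.698138e-01
103.0 1.693062e-01
104.0 1.688060e-01
105.0 1.683130e-01
106.0 1.678267e-01
107.0 1.673471e-01
108.0 1.668739e-01
109.0 1.664069e-01
110.0 1.659459e-01
111.0 1.654908e-01
112.0 1.650413e-01
113.0 1.645972e-01
114.0 1.641585e-01
115.0 1.637249e-01
116.0 1.632964e-01
117.0 1.628727e-01
118.0 1.624537e-01
119.0 1.620394e-01
120.0 1.616295e-01
121.0 1.612240e-01
122.0 1.608228e-01
123.0 1.604257e-01
124.0 1.600326e-01
125.0 1.596435e-01
126.0 1.592582e-01
127.0 1.588767e-01
128.0 1.584989e-01
129.0 1.581247e-01
130.0 1.577539e-01
131.0 1.573866e-01
132.0 1.570226e-01
133.0 1.566619e-01
134.0 1.563044e-01
135.0 1.559501e-01
136.0 1.555988e-01
137.0 1.552506e-01
138.0 1.549053e-01
139.0 1.545629e-01
140.0 1.542233e-01
141.0 1.538865e-01
142.0 1.535525e-01
143.0 1.532211e-01
144.0 1.528924e-01
145.0 1.525663e-01
146.0 1.522427e-01
147.0 1.519216e-01
148.0 1.516029e-01
149.0 1.512866e-01
150.0 1.509728e-01
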