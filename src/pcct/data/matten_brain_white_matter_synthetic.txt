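# synthetic mass attenuation table for brain_white_matter
# two-term parametric fit (photoelectric + Klein-Nishina) to anchor values
# density_g_cm3: 1.041
# columns: energy_keV  mu_over_rho_cm2_g
10.0 4.674150e+00
11.0 3.564411e+00
12.0 2.793913e+00
13.0 2.242255e+00
14.0 1.836881e+00
15.0 1.532291e+00
16.0 1.298965e+00
17.0 1.117180e+00
18.0 9.734181e-01
19.0 8.582019e-01
20.0 7.647539e-01
21.0 6.881399e-01
22.0 6.247093e-01
23.0 5.717222e-01
24.0 5.270949e-01
25.0 4.892234e-01
26.0 4.568596e-01
27.0 4.290225e-01
28.0 4.049335e-01
29.0 3.839697e-01
30.0 3.656284e-01
31.0 3.495012e-01
32.0 3.352537e-01
33.0 3.226106e-01
34.0 3.113435e-01
35.0 3.012622e-01
36.0 2.922072e-01
37.0 2.840444e-01
38.0 2.766599e-01
39.0 2.699572e-01
40.0 2.638537e-01
41.0 2.582787e-01
42.0 2.531714e-01
43.0 2.484790e-01
44.0 2.441560e-01
45.0 2.401628e-01
46.0 2.364647e-01
47.0 2.330315e-01
48.0 2.298365e-01
49.0 2.268564e-01
50.0 2.240705e-01
51.0 2.214604e-01
52.0 2.190101e-01
53.0 2.167050e-01
54.0 2.145324e-01
55.0 2.124807e-01
56.0 2.105396e-01
57.0 2.086999e-01
58.0 2.069534e-01
59.0 2.052926e-01
60.0 2.037107e-01
61.0 2.022016e-01
62.0 2.007599e-01
63.0 1.993805e-01
64.0 1.980590e-01
65.0 1.967911e-01
66.0 1.955731e-01
67.0 1.944016e-01
68.0 1.932734e-01
69.0 1.921856e-01
70.0 1.911357e-01
71.0 1.901212e-01
72.0 1.891399e-01
73.0 1.881897e-01
74.0 1.872687e-01
75.0 1.863753e-01
76.0 1.855078e-01
77.0 1.846647e-01
78.0 1.838446e-01
79.0 1.830464e-01
80.0 1.822687e-01
81.0 1.815106e-01
82.0 1.807709e-01
83.0 1.800488e-01
84.0 1.793433e-01
85.0 1.786536e-01
86.0 1.779791e-01
87.0 1.773188e-01
88.0 1.766723e-01
89.0 1.760388e-01
90.0 1.754177e-01
91.0 1.748085e-01
92.0 1.742108e-01
93.0 1.736239e-01
94.0 1.730475e-01
95.0 1.724811e-01
96.0 1.719243e-01
97.0 1.713767e-01
98.0 1.708380e-01
99.0 1.703078e-01
100.0 1.697859e-01
101.0 1.692718e-01
102.0 1.687654e-01
103.0 1.682663e-01
104.0 1.677743e-01
105.0 1.672892e-01
106.0 1.668107e-01
107.0 1.663386e-01
108.0 1.658726e-01
109.0 1.654127e-01
110.0 1.649586e-01
111.0 1.645101e-01
112.0 1.640671e-01
113.0 1.636294e-01
114.0 1.631968e-01
115.0 1.627692e-01
116.0 1.623464e-01
117.0 1.619284e-01
118.0 1.615150e-01
119.0 1.611060e-01
120.0 1.607014e-01
121.0 1.603011e-01
122.0 1.599048e-01
123.0 1.595126e-01
124.0 1.591244e-01
125.0 1.587399e-01
126.0 1.583592e-01
127.0 1.579822e-01
128.0 1.576087e-01
129.0 1.572387e-01
130.0 1.568721e-01
131.0 1.565089e-01
132.0 1.561489e-01
133.0 1.557922e-01
134.0 1.554385e-01
135.0 1.550880e-01
136.0 1.547404e-01
137.0 1.543958e-01
138.0 1.540540e-01
139.0 1.537151e-01
140.0 1.533790e-01
141.0 1.530455e-01
142.0 1.527148e-01
143.0 1.523867e-01
144.0 1.520611e-01
145.0 1.517381e-01
146.0 1.514176e-01
147.0 1.510995e-01
148.0 1.507838e-01
149.0 1.504705e-01
150.0 1.501595e-01
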