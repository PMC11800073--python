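# synthetic mass attenuation table for air
# two-term parametric fit (photoelectric + Klein-Nishina) to anchor values
# density_g_cm3: 0.0012
# columns: energy_keV  mu_over_rho_cm2_g
10.0 4.847579e+00
11.0 3.689725e+00
12.0 2.885853e+00
13.0 2.310329e+00
14.0 1.887445e+00
15.0 1.569724e+00
16.0 1.326362e+00
17.0 1.136781e+00
18.0 9.868730e-01
19.0 8.667509e-01
20.0 7.693420e-01
21.0 6.894976e-01
22.0 6.234087e-01
23.0 5.682162e-01
24.0 5.217458e-01
25.0 4.823239e-01
26.0 4.486483e-01
27.0 4.196952e-01
28.0 3.946522e-01
29.0 3.728694e-01
30.0 3.538223e-01
31.0 3.370847e-01
32.0 3.223077e-01
33.0 3.092039e-01
34.0 2.975352e-01
35.0 2.871031e-01
36.0 2.777412e-01
37.0 2.693094e-01
38.0 2.616891e-01
39.0 2.547794e-01
40.0 2.484943e-01
41.0 2.427600e-01
42.0 2.375129e-01
43.0 2.326981e-01
44.0 2.282681e-01
45.0 2.241815e-01
46.0 2.204022e-01
47.0 2.168987e-01
48.0 2.136431e-01
49.0 2.106110e-01
50.0 2.077810e-01
51.0 2.051338e-01
52.0 2.026527e-01
53.0 2.003226e-01
54.0 1.981300e-01
55.0 1.960630e-01
56.0 1.941109e-01
57.0 1.922641e-01
58.0 1.905138e-01
59.0 1.888524e-01
60.0 1.872728e-01
61.0 1.857687e-01
62.0 1.843343e-01
63.0 1.829644e-01
64.0 1.816543e-01
65.0 1.803996e-01
66.0 1.791965e-01
67.0 1.780414e-01
68.0 1.769310e-01
69.0 1.758623e-01
70.0 1.748326e-01
71.0 1.738393e-01
72.0 1.728802e-01
73.0 1.719531e-01
74.0 1.710560e-01
75.0 1.701872e-01
76.0 1.693449e-01
77.0 1.685277e-01
78.0 1.677341e-01
79.0 1.669627e-01
80.0 1.662124e-01
81.0 1.654821e-01
82.0 1.647705e-01
83.0 1.640769e-01
84.0 1.634002e-01
85.0 1.627396e-01
86.0 1.620943e-01
87.0 1.614636e-01
88.0 1.608467e-01
89.0 1.602431e-01
90.0 1.596520e-01
91.0 1.590730e-01
92.0 1.585054e-01
93.0 1.579489e-01
94.0 1.574029e-01
95.0 1.568669e-01
96.0 1.563406e-01
97.0 1.558236e-01
98.0 1.553155e-01
99.0 1.548159e-01
100.0 1.543245e-01
101.0 1.538410e-01
102.0 1.533651e-01
103.0 1.528965e-01
104.0 1.524350e-01
105.0 1.519803e-01
106.0 1.515322e-01
107.0 1.510904e-01
108.0 1.506548e-01
109.0 1.502251e-01
110.0 1.498011e-01
111.0 1.493827e-01
112.0 1.489697e-01
113.0 1.485618e-01
114.0 1.481591e-01
115.0 1.477612e-01
116.0 1.473681e-01
117.0 1.469797e-01
118.0 1.465957e-01
119.0 1.462161e-01
120.0 1.458407e-01
121.0 1.454695e-01
122.0 1.451023e-01
123.0 1.447390e-01
124.0 1.443796e-01
125.0 1.440238e-01
126.0 1.436717e-01
127.0 1.433232e-01
128.0 1.429781e-01
129.0 1.426364e-01
130.0 1.422979e-01
131.0 1.419627e-01
132.0 1.416307e-01
133.0 1.413017e-01
134.0 1.409757e-01
135.0 1.406527e-01
136.0 1.403325e-01
137.0 1.400152e-01
138.0 1.397007e-01
139.0 1.393888e-01
140.0 1.390796e-01
141.0 1.387730e-01
142.0 1.384690e-01
143.0 1.381675e-01
144.0 1.378684e-01
145.0 1.375717e-01
146.0 1.372774e-01
147.0 1.369854e-01
148.0 1.366957e-01
149.0 1.364083e-01
150.0 1.361230e-01
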