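# synthetic mass attenuation table for brain_gray_matter
# two-term parametric fit (photoelectric + Klein-Nishina) to anchor values
# density_g_cm3: 1.045
# columns: energy_keV  mu_over_rho_cm2_g
10.0 4.758687e+00
11.0 3.627837e+00
12.0 2.842688e+00
13.0 2.280543e+00
14.0 1.867467e+00
15.0 1.557094e+00
16.0 1.319342e+00
17.0 1.134111e+00
18.0 9.876277e-01
19.0 8.702331e-01
20.0 7.750211e-01
21.0 6.969633e-01
22.0 6.323398e-01
23.0 5.783585e-01
24.0 5.328960e-01
25.0 4.943178e-01
26.0 4.613520e-01
27.0 4.329990e-01
28.0 4.084653e-01
29.0 3.871162e-01
30.0 3.684394e-01
31.0 3.520187e-01
32.0 3.375134e-01
33.0 3.246428e-01
34.0 3.131744e-01
35.0 3.029143e-01
36.0 2.936999e-01
37.0 2.853945e-01
38.0 2.778822e-01
39.0 2.710645e-01
40.0 2.648573e-01
41.0 2.591887e-01
42.0 2.539964e-01
43.0 2.492269e-01
44.0 2.448337e-01
45.0 2.407765e-01
46.0 2.370199e-01
47.0 2.335331e-01
48.0 2.302890e-01
49.0 2.272638e-01
50.0 2.244364e-01
51.0 2.217881e-01
52.0 2.193025e-01
53.0 2.169648e-01
54.0 2.147619e-01
55.0 2.126822e-01
56.0 2.107152e-01
57.0 2.088514e-01
58.0 2.070824e-01
59.0 2.054007e-01
60.0 2.037993e-01
61.0 2.022721e-01
62.0 2.008134e-01
63.0 1.994182e-01
64.0 1.980818e-01
65.0 1.968000e-01
66.0 1.955690e-01
67.0 1.943853e-01
68.0 1.932456e-01
69.0 1.921471e-01
70.0 1.910870e-01
71.0 1.900630e-01
72.0 1.890727e-01
73.0 1.881141e-01
74.0 1.871851e-01
75.0 1.862842e-01
76.0 1.854096e-01
77.0 1.845598e-01
78.0 1.837335e-01
79.0 1.829293e-01
80.0 1.821460e-01
81.0 1.813825e-01
82.0 1.806378e-01
83.0 1.799108e-01
84.0 1.792008e-01
85.0 1.785069e-01
86.0 1.778283e-01
87.0 1.771642e-01
88.0 1.765140e-01
89.0 1.758770e-01
90.0 1.752527e-01
91.0 1.746404e-01
92.0 1.740397e-01
93.0 1.734500e-01
94.0 1.728709e-01
95.0 1.723020e-01
96.0 1.717428e-01
97.0 1.711929e-01
98.0 1.706520e-01
99.0 1.701198e-01
100.0 1.695959e-01
101.0 1.690800e-01
102.0 1.685718e-01
103.0 1.680710e-01
104.0 1.675774e-01
105.0 1.670908e-01
106.0 1.666108e-01
107.0 1.661374e-01
108.0 1.656701e-01
109.0 1.652090e-01
110.0 1.647537e-01
111.0 1.643041e-01
112.0 1.638600e-01
113.0 1.634213e-01
114.0 1.629877e-01
115.0 1.625592e-01
116.0 1.621357e-01
117.0 1.617168e-01
118.0 1.613026e-01
119.0 1.608930e-01
120.0 1.604877e-01
121.0 1.600867e-01
122.0 1.596898e-01
123.0 1.592970e-01
124.0 1.589082e-01
125.0 1.585232e-01
126.0 1.581421e-01
127.0 1.577646e-01
128.0 1.573907e-01
129.0 1.570203e-01
130.0 1.566533e-01
131.0 1.562897e-01
132.0 1.559295e-01
133.0 1.555724e-01
134.0 1.552185e-01
135.0 1.548676e-01
136.0 1.545198e-01
137.0 1.541750e-01
138.0 1.538330e-01
139.0 1.534939e-01
140.0 1.531576e-01
141.0 1.528240e-01
142.0 1.524931e-01
143.0 1.521649e-01
144.0 1.518392e-01
145.0 1.515161e-01
146.0 1.511955e-01
147.0 1.508773e-01
148.0 1.505616e-01
149.0 1.502482e-01
150.0 1.499372e-01
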