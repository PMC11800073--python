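# synthetic mass attenuation table for adipose
# two-term parametric fit (photoelectric + Klein-Nishina) to anchor values
# density_g_cm3: 0.95
# columns: energy_keV  mu_over_rho_cm2_g
10.0 3.024380e+00
11.0 2.325215e+00
12.0 1.839695e+00
13.0 1.491993e+00
14.0 1.236417e+00
15.0 1.044314e+00
16.0 8.970926e-01
17.0 7.823325e-01
18.0 6.915201e-01
19.0 6.186874e-01
20.0 5.595660e-01
21.0 5.110484e-01
22.0 4.708356e-01
23.0 4.372022e-01
24.0 4.088358e-01
25.0 3.847263e-01
26.0 3.640877e-01
27.0 3.463022e-01
28.0 3.308793e-01
29.0 3.174267e-01
30.0 3.056280e-01
31.0 2.952258e-01
32.0 2.860095e-01
33.0 2.778056e-01
34.0 2.704705e-01
35.0 2.638842e-01
36.0 2.579463e-01
37.0 2.525722e-01
38.0 2.476903e-01
39.0 2.432398e-01
40.0 2.391685e-01
41.0 2.354320e-01
42.0 2.319919e-01
43.0 2.288150e-01
44.0 2.258725e-01
45.0 2.231396e-01
46.0 2.205943e-01
47.0 2.182176e-01
48.0 2.159927e-01
49.0 2.139049e-01
50.0 2.119410e-01
51.0 2.100897e-01
52.0 2.083405e-01
53.0 2.066845e-01
54.0 2.051135e-01
55.0 2.036203e-01
56.0 2.021984e-01
57.0 2.008419e-01
58.0 1.995456e-01
59.0 1.983048e-01
60.0 1.971152e-01
61.0 1.959730e-01
62.0 1.948747e-01
63.0 1.938171e-01
64.0 1.927974e-01
65.0 1.918129e-01
66.0 1.908613e-01
67.0 1.899403e-01
68.0 1.890479e-01
69.0 1.881825e-01
70.0 1.873421e-01
71.0 1.865254e-01
72.0 1.857310e-01
73.0 1.849574e-01
74.0 1.842036e-01
75.0 1.834683e-01
76.0 1.827506e-01
77.0 1.820496e-01
78.0 1.813643e-01
79.0 1.806939e-01
80.0 1.800377e-01
81.0 1.793950e-01
82.0 1.787651e-01
83.0 1.781475e-01
84.0 1.775414e-01
85.0 1.769465e-01
86.0 1.763622e-01
87.0 1.757880e-01
88.0 1.752236e-01
89.0 1.746684e-01
90.0 1.741222e-01
91.0 1.735845e-01
92.0 1.730551e-01
93.0 1.725336e-01
94.0 1.720197e-01
95.0 1.715131e-01
96.0 1.710136e-01
97.0 1.705209e-01
98.0 1.700348e-01
99.0 1.695550e-01
100.0 1.690814e-01
101.0 1.686137e-01
102.0 1.681518e-01
103.0 1.676954e-01
104.0 1.672444e-01
105.0 1.667987e-01
106.0 1.663580e-01
107.0 1.659223e-01
108.0 1.654914e-01
109.0 1.650651e-01
110.0 1.646434e-01
111.0 1.642261e-01
112.0 1.638131e-01
113.0 1.634042e-01
114.0 1.629995e-01
115.0 1.625987e-01
116.0 1.622018e-01
117.0 1.618087e-01
118.0 1.614193e-01
119.0 1.610335e-01
120.0 1.606513e-01
121.0 1.602724e-01
122.0 1.598970e-01
123.0 1.595249e-01
124.0 1.591560e-01
125.0 1.587903e-01
126.0 1.584277e-01
127.0 1.580682e-01
128.0 1.577116e-01
129.0 1.573579e-01
130.0 1.570071e-01
131.0 1.566592e-01
132.0 1.563140e-01
133.0 1.559715e-01
134.0 1.556316e-01
135.0 1.552944e-01
136.0 1.549598e-01
137.0 1.546277e-01
138.0 1.542981e-01
139.0 1.539709e-01
140.0 1.536461e-01
141.0 1.533237e-01
142.0 1.530036e-01
143.0 1.526858e-01
144.0 1.523702e-01
145.0 1.520569e-01
146.0 1.517458e-01
147.0 1.514368e-01
148.0 1.511299e-01
149.0 1.508251e-01
150.0 1.505224e-01
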