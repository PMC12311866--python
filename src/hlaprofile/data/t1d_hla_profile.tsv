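index	allele	hla_class	n_countries	r_prime
1	A*01:01	I	11	-1.064
2	A*02:01	I	11	0.280
3	A*02:05	I	9	1.317
4	A*03:01	I	11	0.477
5	A*11:01	I	11	-0.012
6	A*23:01	I	11	-0.156
7	A*24:02	I	11	0.205
8	A*25:01	I	12	-0.088
9	A*26:01	I	11	-0.677
10	A*29:01	I	11	0.550
11	A*29:02	I	11	0.088
12	A*30:01	I	11	-0.163
13	A*30:02	I	12	0.036
14	A*31:01	I	9	0.203
15	A*32:01	I	12	-0.386
16	A*33:01	I	10	1.032
17	A*33:03	I	9	-0.068
18	A*36:01	I	10	1.058
19	A*68:01	I	11	-0.295
20	A*68:02	I	10	-0.091
21	B*07:02	I	10	-0.153
22	B*08:01	I	12	-0.361
23	B*13:02	I	11	-0.392
24	B*14:01	I	11	0.697
25	B*14:02	I	10	0.861
26	B*15:01	I	10	0.092
27	B*15:17	I	9	0.499
28	B*15:18	I	9	-0.065
29	B*18:01	I	12	0.009
30	B*27:02	I	10	0.655
31	B*27:05	I	12	0.177
32	B*35:01	I	11	0.723
33	B*35:02	I	9	0.324
34	B*35:03	I	9	0.054
35	B*35:08	I	9	0.020
36	B*37:01	I	10	0.150
37	B*38:01	I	9	0.604
38	B*39:01	I	11	-0.061
39	B*39:06	I	9	0.360
40	B*40:01	I	12	0.375
41	B*40:02	I	12	0.054
42	B*41:01	I	11	0.444
43	B*41:02	I	10	0.254
44	B*44:02	I	12	-0.537
45	B*44:03	I	12	-0.176
46	B*44:05	I	9	0.067
47	B*45:01	I	10	-0.114
48	B*47:01	I	11	0.481
49	B*49:01	I	11	0.428
50	B*50:01	I	10	0.827
51	B*51:01	I	10	-0.136
52	B*52:01	I	10	-0.214
53	B*55:01	I	11	-0.211
54	B*56:01	I	9	0.828
55	B*57:01	I	12	-0.380
56	B*58:01	I	9	0.394
57	C*01:02	I	9	0.939
58	C*03:03	I	9	0.729
59	C*04:01	I	9	0.280
60	C*05:01	I	9	-0.093
61	C*06:02	I	9	-0.916
62	C*07:01	I	9	-0.630
63	C*07:02	I	9	0.326
64	C*07:04	I	9	-1.020
65	C*12:02	I	9	-0.337
66	C*12:03	I	9	-0.315
67	C*14:02	I	9	-0.443
68	C*15:02	I	9	-0.004
69	C*16:01	I	9	-0.049
70	DPB1*01:01	II	11	0.596
71	DPB1*02:01	II	11	-0.198
72	DPB1*02:02	II	10	0.132
73	DPB1*03:01	II	11	0.331
74	DPB1*04:01	II	11	0.066
75	DPB1*04:02	II	11	-0.075
76	DPB1*05:01	II	11	0.557
77	DPB1*06:01	II	10	-0.047
78	DPB1*09:01	II	9	0.427
79	DPB1*10:01	II	10	-0.352
80	DPB1*11:01	II	9	0.337
81	DPB1*13:01	II	10	-0.790
82	DPB1*14:01	II	11	-0.282
83	DPB1*17:01	II	9	-0.038
84	DPB1*19:01	II	11	0.158
85	DQB1*02:01	II	12	0.176
86	DQB1*02:02	II	11	-0.132
87	DQB1*03:01	II	13	-0.648
88	DQB1*03:02	II	13	1.031
89	DQB1*03:03	II	13	0.233
90	DQB1*04:02	II	13	0.501
91	DQB1*05:01	II	13	-0.297
92	DQB1*05:02	II	10	-0.123
93	DQB1*05:03	II	12	-0.111
94	DQB1*06:01	II	11	-0.503
95	DQB1*06:02	II	14	0.198
96	DQB1*06:03	II	13	0.129
97	DQB1*06:04	II	12	-0.559
98	DQB1*06:09	II	9	-0.084
99	DRB1*01:01	II	14	0.092
100	DRB1*01:02	II	11	0.578
101	DRB1*01:03	II	11	0.056
102	DRB1*03:01	II	13	0.031
103	DRB1*04:01	II	13	0.131
104	DRB1*04:02	II	11	0.183
105	DRB1*04:03	II	12	0.021
106	DRB1*04:04	II	13	0.160
107	DRB1*04:05	II	9	0.563
108	DRB1*04:07	II	12	0.058
109	DRB1*04:08	II	9	0.547
110	DRB1*07:01	II	12	-0.369
111	DRB1*08:01	II	13	0.553
112	DRB1*08:03	II	11	0.089
113	DRB1*09:01	II	12	0.225
114	DRB1*10:01	II	14	-0.083
115	DRB1*11:01	II	14	-0.281
116	DRB1*11:02	II	12	0.443
117	DRB1*11:03	II	12	-0.231
118	DRB1*11:04	II	12	-0.120
119	DRB1*12:01	II	13	1.177
120	DRB1*13:01	II	14	0.381
121	DRB1*13:02	II	14	-0.266
122	DRB1*13:03	II	10	-0.194
123	DRB1*13:05	II	10	-0.142
124	DRB1*14:01	II	14	-0.126
125	DRB1*15:01	II	13	0.059
126	DRB1*15:02	II	10	-0.214
127	DRB1*16:01	II	10	-0.260
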