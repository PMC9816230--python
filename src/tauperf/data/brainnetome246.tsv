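index	label	compartment	hemisphere	is_table2_target	table2_percent_diff	table2_p_fdr
1	A8m_L	Frontal lobe	L	0		
2	A8m_R	Frontal lobe	R	0		
3	A8dl_L	Frontal lobe	L	0		
4	A8dl_R	Frontal lobe	R	0		
5	A9l_L	Frontal lobe	L	0		
6	A9l_R	Frontal lobe	R	0		
7	A6dl_L	Frontal lobe	L	0		
8	A6dl_R	Frontal lobe	R	0		
9	A6m_L	Frontal lobe	L	0		
10	A6m_R	Frontal lobe	R	0		
11	A9m_L	Frontal lobe	L	0		
12	A9m_R	Frontal lobe	R	1	-12.78	0.0032
13	A10m_L	Frontal lobe	L	0		
14	A10m_R	Frontal lobe	R	1	-12.45	0.0032
15	A9/46d_L	Frontal lobe	L	0		
16	A9/46d_R	Frontal lobe	R	0		
17	IFJ_L	Frontal lobe	L	0		
18	IFJ_R	Frontal lobe	R	0		
19	A46_L	Frontal lobe	L	0		
20	A46_R	Frontal lobe	R	0		
21	A9/46v_L	Frontal lobe	L	0		
22	A9/46v_R	Frontal lobe	R	0		
23	A8vl_L	Frontal lobe	L	0		
24	A8vl_R	Frontal lobe	R	0		
25	A6vl_L	Frontal lobe	L	0		
26	A6vl_R	Frontal lobe	R	0		
27	A10l_L	Frontal lobe	L	0		
28	A10l_R	Frontal lobe	R	0		
29	A44d_L	Frontal lobe	L	1	-10.99	0.0018
30	A44d_R	Frontal lobe	R	0		
31	IFS_L	Frontal lobe	L	1	-8.96	0.0098
32	IFS_R	Frontal lobe	R	0		
33	A45c_L	Frontal lobe	L	0		
34	A45c_R	Frontal lobe	R	0		
35	A45r_L	Frontal lobe	L	0		
36	A45r_R	Frontal lobe	R	0		
37	A44op_L	Frontal lobe	L	0		
38	A44op_R	Frontal lobe	R	0		
39	A44v_L	Frontal lobe	L	0		
40	A44v_R	Frontal lobe	R	0		
41	A14m_L	Frontal lobe	L	0		
42	A14m_R	Frontal lobe	R	0		
43	A12/47o_L	Frontal lobe	L	0		
44	A12/47o_R	Frontal lobe	R	0		
45	A11l_L	Frontal lobe	L	0		
46	A11l_R	Frontal lobe	R	0		
47	A11m_L	Frontal lobe	L	0		
48	A11m_R	Frontal lobe	R	0		
49	A13_L	Frontal lobe	L	0		
50	A13_R	Frontal lobe	R	0		
51	A12/47l_L	Frontal lobe	L	0		
52	A12/47l_R	Frontal lobe	R	0		
53	A4hf_L	Frontal lobe	L	0		
54	A4hf_R	Frontal lobe	R	0		
55	A6cdl_L	Frontal lobe	L	0		
56	A6cdl_R	Frontal lobe	R	0		
57	A4ul_L	Frontal lobe	L	0		
58	A4ul_R	Frontal lobe	R	0		
59	A4t_L	Frontal lobe	L	0		
60	A4t_R	Frontal lobe	R	0		
61	A4tl_L	Frontal lobe	L	0		
62	A4tl_R	Frontal lobe	R	0		
63	A6cvl_L	Frontal lobe	L	0		
64	A6cvl_R	Frontal lobe	R	0		
65	A1/2/3ll_L	Frontal lobe	L	0		
66	A1/2/3ll_R	Frontal lobe	R	0		
67	A4ll_L	Frontal lobe	L	0		
68	A4ll_R	Frontal lobe	R	0		
69	A38m_L	Temporal lobe	L	1	-10.34	0.0054
70	A38m_R	Temporal lobe	R	0		
71	A41/42_L	Temporal lobe	L	0		
72	A41/42_R	Temporal lobe	R	0		
73	TE1.0/TE1.2_L	Temporal lobe	L	0		
74	TE1.0/TE1.2_R	Temporal lobe	R	0		
75	A22c_L	Temporal lobe	L	0		
76	A22c_R	Temporal lobe	R	0		
77	A38l_L	Temporal lobe	L	1	-14.23	0.0018
78	A38l_R	Temporal lobe	R	1	-11.38	0.0021
79	A22r_L	Temporal lobe	L	0		
80	A22r_R	Temporal lobe	R	0		
81	A21c_L	Temporal lobe	L	0		
82	A21c_R	Temporal lobe	R	0		
83	A21r_L	Temporal lobe	L	0		
84	A21r_R	Temporal lobe	R	0		
85	A37dl_L	Temporal lobe	L	0		
86	A37dl_R	Temporal lobe	R	0		
87	aSTS_L	Temporal lobe	L	0		
88	aSTS_R	Temporal lobe	R	0		
89	A20iv_L	Temporal lobe	L	0		
90	A20iv_R	Temporal lobe	R	0		
91	A37elv_L	Temporal lobe	L	0		
92	A37elv_R	Temporal lobe	R	0		
93	A20r_L	Temporal lobe	L	0		
94	A20r_R	Temporal lobe	R	0		
95	A20il_L	Temporal lobe	L	0		
96	A20il_R	Temporal lobe	R	0		
97	A37vl_L	Temporal lobe	L	0		
98	A37vl_R	Temporal lobe	R	0		
99	A20cl_L	Temporal lobe	L	0		
100	A20cl_R	Temporal lobe	R	0		
101	A20cv_L	Temporal lobe	L	0		
102	A20cv_R	Temporal lobe	R	0		
103	A20rv_L	Temporal lobe	L	0		
104	A20rv_R	Temporal lobe	R	0		
105	A37mv_L	Temporal lobe	L	0		
106	A37mv_R	Temporal lobe	R	0		
107	A37lv_L	Temporal lobe	L	0		
108	A37lv_R	Temporal lobe	R	0		
109	A35/36r_L	Temporal lobe	L	0		
110	A35/36r_R	Temporal lobe	R	0		
111	A35/36c_L	Temporal lobe	L	0		
112	A35/36c_R	Temporal lobe	R	0		
113	TL_L	Temporal lobe	L	0		
114	TL_R	Temporal lobe	R	0		
115	A28/34_L	Temporal lobe	L	0		
116	A28/34_R	Temporal lobe	R	0		
117	TI_L	Temporal lobe	L	0		
118	TI_R	Temporal lobe	R	0		
119	TH_L	Temporal lobe	L	1	-9.45	0.0057
120	TH_R	Temporal lobe	R	0		
121	rpSTS_L	Temporal lobe	L	0		
122	rpSTS_R	Temporal lobe	R	0		
123	cpSTS_L	Temporal lobe	L	0		
124	cpSTS_R	Temporal lobe	R	0		
125	A7r_L	Parietal lobe	L	0		
126	A7r_R	Parietal lobe	R	0		
127	A7c_L	Parietal lobe	L	0		
128	A7c_R	Parietal lobe	R	0		
129	A5l_L	Parietal lobe	L	0		
130	A5l_R	Parietal lobe	R	0		
131	A7pc_L	Parietal lobe	L	0		
132	A7pc_R	Parietal lobe	R	0		
133	A7ip_L	Parietal lobe	L	0		
134	A7ip_R	Parietal lobe	R	0		
135	A39c_L	Parietal lobe	L	0		
136	A39c_R	Parietal lobe	R	0		
137	A39rd_L	Parietal lobe	L	1	-9.62	0.0037
138	A39rd_R	Parietal lobe	R	0		
139	A40rd_L	Parietal lobe	L	0		
140	A40rd_R	Parietal lobe	R	0		
141	A40c_L	Parietal lobe	L	0		
142	A40c_R	Parietal lobe	R	0		
143	A39rv_L	Parietal lobe	L	0		
144	A39rv_R	Parietal lobe	R	0		
145	A40rv_L	Parietal lobe	L	0		
146	A40rv_R	Parietal lobe	R	0		
147	A7m_L	Parietal lobe	L	0		
148	A7m_R	Parietal lobe	R	0		
149	A5m_L	Parietal lobe	L	0		
150	A5m_R	Parietal lobe	R	0		
151	dmPOS_L	Parietal lobe	L	0		
152	dmPOS_R	Parietal lobe	R	0		
153	A31_L	Parietal lobe	L	0		
154	A31_R	Parietal lobe	R	0		
155	A1/2/3ulhf_L	Parietal lobe	L	0		
156	A1/2/3ulhf_R	Parietal lobe	R	0		
157	A1/2/3tonIa_L	Parietal lobe	L	0		
158	A1/2/3tonIa_R	Parietal lobe	R	0		
159	A2_L	Parietal lobe	L	0		
160	A2_R	Parietal lobe	R	0		
161	A1/2/3tru_L	Parietal lobe	L	0		
162	A1/2/3tru_R	Parietal lobe	R	0		
163	G_L	Insula	L	0		
164	G_R	Insula	R	0		
165	vIa_L	Insula	L	0		
166	vIa_R	Insula	R	0		
167	dIa_L	Insula	L	0		
168	dIa_R	Insula	R	0		
169	vId/vIg_L	Insula	L	0		
170	vId/vIg_R	Insula	R	0		
171	dIg_L	Insula	L	0		
172	dIg_R	Insula	R	0		
173	dId_L	Insula	L	0		
174	dId_R	Insula	R	0		
175	A23d_L	Limbic	L	0		
176	A23d_R	Limbic	R	0		
177	A24rv_L	Limbic	L	0		
178	A24rv_R	Limbic	R	0		
179	A32p_L	Limbic	L	0		
180	A32p_R	Limbic	R	1	-13.16	0.0035
181	A23v_L	Limbic	L	0		
182	A23v_R	Limbic	R	0		
183	A24cd_L	Limbic	L	0		
184	A24cd_R	Limbic	R	1	-13.92	0.0099
185	A23c_L	Limbic	L	0		
186	A23c_R	Limbic	R	0		
187	A32sg_L	Limbic	L	0		
188	A32sg_R	Limbic	R	1	-14.15	0.0030
189	cLinG_L	Occipital lobe	L	0		
190	cLinG_R	Occipital lobe	R	0		
191	rCunG_L	Occipital lobe	L	0		
192	rCunG_R	Occipital lobe	R	0		
193	cCunG_L	Occipital lobe	L	0		
194	cCunG_R	Occipital lobe	R	0		
195	rLinG_L	Occipital lobe	L	0		
196	rLinG_R	Occipital lobe	R	0		
197	vmPOS_L	Occipital lobe	L	0		
198	vmPOS_R	Occipital lobe	R	0		
199	mOccG_L	Occipital lobe	L	0		
200	mOccG_R	Occipital lobe	R	0		
201	V5/MT+_L	Occipital lobe	L	0		
202	V5/MT+_R	Occipital lobe	R	0		
203	OPC_L	Occipital lobe	L	0		
204	OPC_R	Occipital lobe	R	0		
205	iOccG_L	Occipital lobe	L	0		
206	iOccG_R	Occipital lobe	R	0		
207	msOccG_L	Occipital lobe	L	0		
208	msOccG_R	Occipital lobe	R	0		
209	lsOccG_L	Occipital lobe	L	0		
210	lsOccG_R	Occipital lobe	R	0		
211	mAmyg_L	Limbic	L	0		
212	mAmyg_R	Limbic	R	0		
213	lAmyg_L	Limbic	L	0		
214	lAmyg_R	Limbic	R	0		
215	rHipp_L	Limbic	L	0		
216	rHipp_R	Limbic	R	0		
217	cHipp_L	Limbic	L	0		
218	cHipp_R	Limbic	R	0		
219	vCa_L	Basal ganglia	L	0		
220	vCa_R	Basal ganglia	R	1	-14.69	0.0058
221	GP_L	Basal ganglia	L	0		
222	GP_R	Basal ganglia	R	0		
223	NAC_L	Basal ganglia	L	0		
224	NAC_R	Basal ganglia	R	0		
225	vmPu_L	Basal ganglia	L	0		
226	vmPu_R	Basal ganglia	R	0		
227	dCa_L	Basal ganglia	L	1	-28.34	0.0024
228	dCa_R	Basal ganglia	R	1	-27.75	0.0098
229	dlPu_L	Basal ganglia	L	0		
230	dlPu_R	Basal ganglia	R	0		
231	mPFtha_L	Thalamus	L	1	-14.36	0.0026
232	mPFtha_R	Thalamus	R	1	-19.81	0.0003
233	mPMtha_L	Thalamus	L	1	-14.64	0.0017
234	mPMtha_R	Thalamus	R	0		
235	Stha_L	Thalamus	L	0		
236	Stha_R	Thalamus	R	0		
237	rTtha_L	Thalamus	L	1	-21.08	0.0003
238	rTtha_R	Thalamus	R	1	-27.48	4.07E-06
239	PPtha_L	Thalamus	L	0		
240	PPtha_R	Thalamus	R	0		
241	Otha_L	Thalamus	L	0		
242	Otha_R	Thalamus	R	0		
243	cTtha_L	Thalamus	L	0		
244	cTtha_R	Thalamus	R	1	-27.73	0.0059
245	lPFtha_L	Thalamus	L	0		
246	lPFtha_R	Thalamus	R	0		
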