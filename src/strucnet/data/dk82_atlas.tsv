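index	name	abbreviation	hemisphere	tissue_class
0	Bank of the superior temporal sulcus	BSTS	L	cortical
1	Caudal anterior cingulate gyrus	cACG	L	cortical
2	Caudal middle frontal gyrus	cMFG	L	cortical
3	Cuneus	CUN	L	cortical
4	Entorhinal cortex	ENT	L	cortical
5	Fusiform gyrus	FUS	L	cortical
6	Inferior parietal lobule	IPL	L	cortical
7	Inferior temporal gyrus	ITG	L	cortical
8	Isthmus cingulate gyrus	iCG	L	cortical
9	Lateral occipital gyrus	LOG	L	cortical
10	Lateral orbitofrontal gyrus	LOF	L	cortical
11	Lingual gyrus	LING	L	cortical
12	Medial orbitofrontal gyrus	MOF	L	cortical
13	Middle temporal gyrus	MTG	L	cortical
14	Parahippocampal gyrus	PARH	L	cortical
15	Paracentral lobule	paraC	L	cortical
16	Pars opercularis	pOPER	L	cortical
17	Pars orbitalis	pORB	L	cortical
18	Pars triangularis	pTRI	L	cortical
19	Pericalcarine cortex	periCAL	L	cortical
20	Postcentral gyrus	postC	L	cortical
21	Posterior cingulate gyrus	PCG	L	cortical
22	Precentral gyrus	preC	L	cortical
23	Precuneus	PCUN	L	cortical
24	Rostral anterior cingulate gyrus	rACG	L	cortical
25	Rostral middle frontal gyrus	rMFG	L	cortical
26	Superior frontal gyrus	SFG	L	cortical
27	Superior parietal lobule	SPL	L	cortical
28	Superior temporal gyrus	STG	L	cortical
29	Supramarginal gyrus	SMAR	L	cortical
30	Frontal pole	FP	L	cortical
31	Temporal pole	TP	L	cortical
32	Transverse temporal gyrus	TT	L	cortical
33	Insula	INS	L	cortical
34	Thalamus	THAL	L	subcortical
35	Putamen	PUT	L	subcortical
36	Pallidum	PALL	L	subcortical
37	Caudate	CAUD	L	subcortical
38	Hippocampus	HIPP	L	subcortical
39	Amygdala	AMYG	L	subcortical
40	Nucleus accumbens	ACCU	L	subcortical
41	Bank of the superior temporal sulcus	BSTS	R	cortical
42	Caudal anterior cingulate gyrus	cACG	R	cortical
43	Caudal middle frontal gyrus	cMFG	R	cortical
44	Cuneus	CUN	R	cortical
45	Entorhinal cortex	ENT	R	cortical
46	Fusiform gyrus	FUS	R	cortical
47	Inferior parietal lobule	IPL	R	cortical
48	Inferior temporal gyrus	ITG	R	cortical
49	Isthmus cingulate gyrus	iCG	R	cortical
50	Lateral occipital gyrus	LOG	R	cortical
51	Lateral orbitofrontal gyrus	LOF	R	cortical
52	Lingual gyrus	LING	R	cortical
53	Medial orbitofrontal gyrus	MOF	R	cortical
54	Middle temporal gyrus	MTG	R	cortical
55	Parahippocampal gyrus	PARH	R	cortical
56	Paracentral lobule	paraC	R	cortical
57	Pars opercularis	pOPER	R	cortical
58	Pars orbitalis	pORB	R	cortical
59	Pars triangularis	pTRI	R	cortical
60	Pericalcarine cortex	periCAL	R	cortical
61	Postcentral gyrus	postC	R	cortical
62	Posterior cingulate gyrus	PCG	R	cortical
63	Precentral gyrus	preC	R	cortical
64	Precuneus	PCUN	R	cortical
65	Rostral anterior cingulate gyrus	rACG	R	cortical
66	Rostral middle frontal gyrus	rMFG	R	cortical
67	Superior frontal gyrus	SFG	R	cortical
68	Superior parietal lobule	SPL	R	cortical
69	Superior temporal gyrus	STG	R	cortical
70	Supramarginal gyrus	SMAR	R	cortical
71	Frontal pole	FP	R	cortical
72	Temporal pole	TP	R	cortical
73	Transverse temporal gyrus	TT	R	cortical
74	Insula	INS	R	cortical
75	Thalamus	THAL	R	subcortical
76	Putamen	PUT	R	subcortical
77	Pallidum	PALL	R	subcortical
78	Caudate	CAUD	R	subcortical
79	Hippocampus	HIPP	R	subcortical
80	Amygdala	AMYG	R	subcortical
81	Nucleus accumbens	ACCU	R	subcortical
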