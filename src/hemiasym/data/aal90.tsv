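index	name	abbrev	hemisphere
0	Precentral gyrus	PreCG	L
1	Precentral gyrus	PreCG	R
2	Superior frontal gyrus, dorsolateral	SFGdor	L
3	Superior frontal gyrus, dorsolateral	SFGdor	R
4	Superior frontal gyrus, orbital part	ORBsup	L
5	Superior frontal gyrus, orbital part	ORBsup	R
6	Middle frontal gyrus	MFG	L
7	Middle frontal gyrus	MFG	R
8	Middle frontal gyrus, orbital part	ORBmid	L
9	Middle frontal gyrus, orbital part	ORBmid	R
10	Inferior frontal gyrus, opercular part	IFGoperc	L
11	Inferior frontal gyrus, opercular part	IFGoperc	R
12	Inferior frontal gyrus, triangular part	IFGtriang	L
13	Inferior frontal gyrus, triangular part	IFGtriang	R
14	Inferior frontal gyrus, orbital part	ORBinf	L
15	Inferior frontal gyrus, orbital part	ORBinf	R
16	Rolandic operculum	ROL	L
17	Rolandic operculum	ROL	R
18	Supplementary motor area	SMA	L
19	Supplementary motor area	SMA	R
20	Olfactory cortex	OLF	L
21	Olfactory cortex	OLF	R
22	Superior frontal gyrus, medial	SFGmed	L
23	Superior frontal gyrus, medial	SFGmed	R
24	Superior frontal gyrus, medial orbital	ORBsupmed	L
25	Superior frontal gyrus, medial orbital	ORBsupmed	R
26	Gyrus rectus	REC	L
27	Gyrus rectus	REC	R
28	Insula	INS	L
29	Insula	INS	R
30	Anterior cingulate and paracingulate gyri	ACG	L
31	Anterior cingulate and paracingulate gyri	ACG	R
32	Median cingulate and paracingulate gyri	DCG	L
33	Median cingulate and paracingulate gyri	DCG	R
34	Posterior cingulate gyrus	PCG	L
35	Posterior cingulate gyrus	PCG	R
36	Hippocampus	HIP	L
37	Hippocampus	HIP	R
38	Parahippocampal gyrus	PHG	L
39	Parahippocampal gyrus	PHG	R
40	Amygdala	AMYG	L
41	Amygdala	AMYG	R
42	Calcarine fissure and surrounding cortex	CAL	L
43	Calcarine fissure and surrounding cortex	CAL	R
44	Cuneus	CUN	L
45	Cuneus	CUN	R
46	Lingual gyrus	LING	L
47	Lingual gyrus	LING	R
48	Superior occipital gyrus	SOG	L
49	Superior occipital gyrus	SOG	R
50	Middle occipital gyrus	MOG	L
51	Middle occipital gyrus	MOG	R
52	Inferior occipital gyrus	IOG	L
53	Inferior occipital gyrus	IOG	R
54	Fusiform gyrus	FFG	L
55	Fusiform gyrus	FFG	R
56	Postcentral gyrus	PoCG	L
57	Postcentral gyrus	PoCG	R
58	Superior parietal gyrus	SPG	L
59	Superior parietal gyrus	SPG	R
60	Inferior parietal lobule	IPL	L
61	Inferior parietal lobule	IPL	R
62	Supramarginal gyrus	SMG	L
63	Supramarginal gyrus	SMG	R
64	Angular gyrus	ANG	L
65	Angular gyrus	ANG	R
66	Precuneus	PCUN	L
67	Precuneus	PCUN	R
68	Paracentral lobule	PCL	L
69	Paracentral lobule	PCL	R
70	Caudate nucleus	CAU	L
71	Caudate nucleus	CAU	R
72	Lenticular nucleus, putamen	PUT	L
73	Lenticular nucleus, putamen	PUT	R
74	Lenticular nucleus, pallidum	PAL	L
75	Lenticular nucleus, pallidum	PAL	R
76	Thalamus	THA	L
77	Thalamus	THA	R
78	Heschl gyrus	HES	L
79	Heschl gyrus	HES	R
80	Superior temporal gyrus	STG	L
81	Superior temporal gyrus	STG	R
82	Temporal pole: superior temporal gyrus	TPOsup	L
83	Temporal pole: superior temporal gyrus	TPOsup	R
84	Middle temporal gyrus	MTG	L
85	Middle temporal gyrus	MTG	R
86	Temporal pole: middle temporal gyrus	TPOmid	L
87	Temporal pole: middle temporal gyrus	TPOmid	R
88	Inferior temporal gyrus	ITG	L
89	Inferior temporal gyrus	ITG	R
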