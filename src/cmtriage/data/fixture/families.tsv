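family_id	subgroup	era
1	CMT2	prior
102	CMT2	ngs
11	CMT2	ngs
118	CMT1	prior
123	CMT2	ngs
124	CMT1	prior
136	CMT1	prior
142	CMT1	ngs
148	CMT1	prior
155	CMT1	prior
17	CMT1	prior
225	CMT1	prior
231	CMT2	ngs
252	CMT1	ngs
256	CMT1	prior
257	CMT2	ngs
258	CMT2	prior
27	unknown	ngs
285	CMT1	ngs
295	CMT1	ngs
309	CMT1	prior
367	CMT1	prior
371	unknown	prior
38	CMT2	prior
39	CMT1	prior
398	CMT2	prior
44	CMT1	prior
5	CMT2	ngs
51	CMT1	prior
54	CMT2	ngs
56	CMT1	prior
62	CMT2	ngs
8	CMT1	prior
82	CMT1	prior
83	ICMT	prior
9	unknown	ngs
90	CMT1	ngs
95	CMT2	ngs
N101	CMT1	ngs
N102	CMT1	ngs
N103	CMT1	ngs
N104	CMT1	ngs
N105	CMT1	ngs
N106	CMT1	ngs
N107	CMT1	ngs
N108	CMT1	ngs
N109	CMT1	ngs
N110	CMT1	ngs
N111	CMT1	ngs
N112	CMT1	ngs
N113	CMT1	ngs
N114	CMT1	ngs
N115	CMT1	ngs
N116	CMT1	ngs
N117	CMT1	ngs
N201	CMT2	ngs
N202	CMT2	ngs
N203	CMT2	ngs
N204	CMT2	ngs
N205	CMT2	ngs
N206	CMT2	ngs
N207	CMT2	ngs
N208	CMT2	ngs
N209	CMT2	ngs
N210	CMT2	ngs
N211	CMT2	ngs
N212	CMT2	ngs
N213	CMT2	ngs
N214	CMT2	ngs
N215	CMT2	ngs
N216	CMT2	ngs
N217	CMT2	ngs
N218	CMT2	ngs
N219	CMT2	ngs
N220	CMT2	ngs
N301	ICMT	ngs
N401	unknown	ngs
N402	unknown	ngs
N403	unknown	ngs
N404	unknown	ngs
N405	unknown	ngs
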