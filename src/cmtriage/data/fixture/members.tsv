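family_id	member_id	sex	affected	genotyped	father_id	mother_id
1	1-1	M	1	1	0	0
1	1-2	F	1	0	0	0
102	102-1	M	1	1	0	0
102	102-2	F	1	1	0	0
102	102-3	F	0	1	0	0
11	11-1	M	1	1	0	0
11	11-2	F	1	0	0	0
118	118-1	M	1	1	0	0
118	118-2	F	1	0	0	0
123	123-1	M	1	1	0	0
124	124-1	M	1	1	0	0
124	124-2	F	1	0	0	0
136	136-1	M	1	1	0	0
136	136-2	F	1	0	0	0
142	142-1	M	1	1	0	0
142	142-2	F	1	0	0	0
142	142-3	F	0	1	0	0
142	142-4	M	0	1	0	0
142	142-5	F	0	1	0	0
148	148-1	M	1	1	0	0
148	148-2	F	1	0	0	0
155	155-1	M	1	1	0	0
155	155-2	F	1	0	0	0
17	17-1	M	1	1	0	0
17	17-2	F	1	0	0	0
225	225-1	M	1	1	0	0
225	225-2	F	1	0	0	0
231	231-1	M	1	1	0	0
252	252-1	M	1	1	0	0
252	252-2	F	1	0	0	0
252	252-3	F	0	1	0	0
252	252-4	M	0	1	0	0
252	252-5	F	0	1	0	0
256	256-1	M	1	1	0	0
256	256-2	F	1	0	0	0
257	257-1	M	1	1	0	0
258	258-1	M	1	1	0	0
258	258-2	F	1	0	0	0
27	27-1	M	1	1	0	0
27	27-2	F	1	0	0	0
285	285-1	F	1	1	0	0
285	285-2	M	1	0	0	0
285	285-3	F	0	1	0	0
285	285-4	M	0	1	0	0
295	295-1	M	1	1	0	0
295	295-2	F	1	0	0	0
295	295-3	F	0	1	0	0
295	295-4	M	0	1	0	0
309	309-1	M	1	1	0	0
309	309-2	F	1	0	0	0
367	367-1	M	1	1	0	0
367	367-2	F	1	0	0	0
371	371-1	M	1	1	0	0
371	371-2	F	1	0	0	0
38	38-1	M	1	1	0	0
38	38-2	F	1	0	0	0
39	39-1	M	1	1	0	0
398	398-1	M	1	1	0	0
398	398-2	F	1	0	0	0
44	44-1	M	1	1	0	0
5	5-1	M	1	1	0	0
5	5-2	M	1	1	0	0
51	51-1	M	1	1	0	0
54	54-1	M	1	1	0	0
54	54-2	F	1	0	0	0
56	56-1	M	1	1	0	0
62	62-1	M	1	1	0	0
8	8-1	M	1	1	0	0
8	8-2	F	1	0	0	0
82	82-1	M	1	1	0	0
83	83-1	M	1	1	0	0
83	83-2	F	1	0	0	0
9	9-1	M	1	1	0	0
9	9-2	F	0	1	0	0
90	90-1	M	1	1	0	0
90	90-2	F	1	0	0	0
95	95-1	M	1	1	0	0
N101	N101-1	M	1	1	0	0
N102	N102-1	M	1	1	0	0
N103	N103-1	M	1	1	0	0
N104	N104-1	M	1	1	0	0
N105	N105-1	M	1	1	0	0
N106	N106-1	M	1	1	0	0
N107	N107-1	M	1	1	0	0
N108	N108-1	M	1	1	0	0
N108	N108-2	F	1	0	0	0
N109	N109-1	M	1	1	0	0
N109	N109-2	F	1	0	0	0
N110	N110-1	M	1	1	0	0
N110	N110-2	F	1	0	0	0
N111	N111-1	M	1	1	0	0
N111	N111-2	F	1	0	0	0
N112	N112-1	M	1	1	0	0
N112	N112-2	F	1	0	0	0
N113	N113-1	M	1	1	0	0
N113	N113-2	F	1	0	0	0
N114	N114-1	M	1	1	0	0
N114	N114-2	F	1	0	0	0
N115	N115-1	M	1	1	0	0
N115	N115-2	F	1	0	0	0
N116	N116-1	M	1	1	0	0
N116	N116-2	F	1	0	0	0
N117	N117-1	M	1	1	0	0
N117	N117-2	F	1	0	0	0
N201	N201-1	M	1	1	0	0
N202	N202-1	M	1	1	0	0
N203	N203-1	M	1	1	0	0
N204	N204-1	M	1	1	0	0
N205	N205-1	M	1	1	0	0
N206	N206-1	M	1	1	0	0
N207	N207-1	M	1	1	0	0
N208	N208-1	M	1	1	0	0
N208	N208-2	F	1	0	0	0
N209	N209-1	M	1	1	0	0
N209	N209-2	F	1	0	0	0
N210	N210-1	M	1	1	0	0
N210	N210-2	F	1	0	0	0
N211	N211-1	M	1	1	0	0
N211	N211-2	F	1	0	0	0
N212	N212-1	M	1	1	0	0
N212	N212-2	F	1	0	0	0
N213	N213-1	M	1	1	0	0
N213	N213-2	F	1	0	0	0
N214	N214-1	M	1	1	0	0
N214	N214-2	F	1	0	0	0
N215	N215-1	M	1	1	0	0
N215	N215-2	F	1	0	0	0
N216	N216-1	M	1	1	0	0
N216	N216-2	F	1	0	0	0
N217	N217-1	M	1	1	0	0
N217	N217-2	F	1	0	0	0
N218	N218-1	M	1	1	0	0
N218	N218-2	F	1	0	0	0
N219	N219-1	M	1	1	0	0
N219	N219-2	F	1	0	0	0
N220	N220-1	M	1	1	0	0
N220	N220-2	F	1	0	0	0
N301	N301-1	M	1	1	0	0
N301	N301-2	F	1	0	0	0
N401	N401-1	M	1	1	0	0
N402	N402-1	M	1	1	0	0
N403	N403-1	M	1	1	0	0
N403	N403-2	F	1	0	0	0
N404	N404-1	M	1	1	0	0
N404	N404-2	F	1	0	0	0
N405	N405-1	M	1	1	0	0
N405	N405-2	F	1	0	0	0
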