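family_id	gene	event	present
17	PMP22	duplication	1
51	PMP22	duplication	1
56	PMP22	duplication	1
82	PMP22	duplication	1
136	PMP22	duplication	1
148	PMP22	duplication	1
155	PMP22	duplication	1
225	PMP22	duplication	1
309	PMP22	duplication	1
367	PMP22	duplication	1
371	PMP22	duplication	1
124	MPZ	duplication	1
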