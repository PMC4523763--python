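label	group	coi_gc_skew	coi_gc_content	rrna28s_gc_skew	rrna28s_gc_content
Valdieri	ingroup	-0.189	40.0	0.051	61.0
Vernante	ingroup	-0.183	39.7	0.053	60.9
Barbarano	ingroup	-0.176	38.2	0.054	59.3
Volpago	ingroup	-0.246	45.9		
Giavera	ingroup	-0.136	38.6	0.044	61.5
Lovran	ingroup	-0.201	41.4	0.051	57.5
Isola Fossara	ingroup	-0.237	43.0	0.047	59.3
Frasassi	ingroup	-0.244	42.5	0.054	59.8
Frosinone	ingroup	-0.244	41.4	0.058	61.1
Randazzo	ingroup	-0.206	40.6	0.056	61.5
Cyprus	ingroup	-0.188	46.8	0.069	61.8
Iran	ingroup	-0.218	43.9	0.040	62.1
Arctogeophilus glacialis	outgroup	-0.254	46.9	0.049	55.7
Clinopodes carinthiacus	outgroup	-0.156	41.1	0.068	61.0
Geophilus alpinus	outgroup	-0.235	47.3	0.080	57.5
Geophilus electricus	outgroup	-0.217	43.4	0.072	58.1
Geophilus flavus	outgroup	-0.232	42.4	0.063	61.5
Tuoba sydneyensis	outgroup	-0.205	39.3	0.055	59.7
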