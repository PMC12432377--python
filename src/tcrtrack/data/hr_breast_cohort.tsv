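patient_id	age	histology	lymph_node_metastasis	grade	preoperative_treatment
Br8	86	ductal	ND	3	letrozole
Br1	52	ductal	no	3	none
Br20	83	ductal	no	2	letrozole
Br23	72	ductal	no	3	none
Br26	65	ductal	no	3	none
Br29	51	ductal	no	1	none
Br4	72	ductal	yes	3	none
Br14	76	ductal	yes	3	none
Br17	57	ductal	yes	3	none
Br21	65	ductal	yes	2	none
Br22	65	ductal	yes	3	none
Br30	71	ductal	yes	3	none
Br31	54	ductal	yes	2	none
Br37	39	ductal	yes	3	none
Br10	63	lobular	no	2	none
Br15	75	lobular	no	2	none
Br16	55	lobular	no	2	none
Br18	67	lobular	no	2	none
Br27	73	lobular	no	2	none
Br19	70	lobular	yes	2	none
Br32	75	lobular	yes	2	letrozole
Br6	65	mucinous	no	2	none
Br7	71	mucinous	no	2	none
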