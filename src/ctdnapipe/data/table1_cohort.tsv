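participant_id	localisation	age_at_diagnosis	sex	stage	os_years	alive_at_end_of_study
P01	Stomach	71	Man	IIIC	1.31	no
P02	Stomach	84	Man	IIB	5.41	yes
P03	Stomach	79	Man	IIB	5.41	yes
P04	Stomach	79	Man	IB	5.39	yes
P05	Stomach	78	Man	IIIC	0.75	no
P06	Stomach	78	Man	IIIC	0.90	no
P07	Stomach	74	Man	IIA	1.81	no
P08	Stomach	64	Man	IB	4.34	no
P09	Stomach	59	Woman	IIIC	1.40	no
P10	Stomach	55	Man	IB	5.02	yes
P11	Oesophagus	75	Man	IIIC	0.99	no
P12	Stomach	65	Woman	IIIC-IV	0.81	no
P13	Stomach	75	Woman	IA	4.62	yes
P14	Stomach	57	Woman	IA	4.84	yes
P15	Stomach	74	Man	IIIC	0.79	no
P16	Stomach	68	Woman	IB	4.72	yes
P17	Oesophagus	56	Woman	IV	0.99	no
P18	Stomach	71	Man	IIA	4.32	yes
P19	Stomach	77	Woman	IIB	4.28	yes
P20	Stomach	43	Man	IIB	4.48	yes
P21	Stomach	76	Man	IIIC	0.22	no
P22	Oesophagus	48	Man	IIIC	1.83	no
P23	Stomach	75	Man	IIA	4.11	yes
P24	Stomach	85	Man	IIIC	1.71	no
P25	Stomach	76	Man	IIIC	0.74	no
P26	Stomach	68	Man	IV	0.45	no
P27	Stomach	81	Man	IIIB	0.88	no
P28	Oesophagus	81	Woman	IIIC	3.66	yes
P29	Stomach	74	Woman	IIIC	1.05	no
P30	Oesophagus	67	Man	IIIC	1.02	no
P31	Oesophagus	74	Woman	IIIC	0.88	no
P32	Stomach	80	Man	IA	3.79	yes
P33	Oesophagus	77	Man	IIIA	2.81	yes
P34	Stomach	36	Woman	IIIC	3.01	yes
P35	Stomach	64	Man	IIIB	2.63	yes
P36	Stomach	62	Woman	IV	2.31	no
P37	Stomach	81	Woman	IB	0.71	no
P38	Stomach	77	Woman	IIA	2.37	yes
P39	Oesophagus	61	Man	IIA	2.49	yes
P40	Stomach	72	Man	IB	2.30	yes
P41	Stomach	87	Man	IIIC	0.57	no
P42	Stomach	61	Man	IA	2.31	yes
P43	Stomach	79	Man	IIIC	1.52	no
P44	Oesophagus	83	Woman	IIIA	0.55	no
P45	Oesophagus	72	Man	IA	2.36	yes
P46	Stomach	64	Man	IB	2.39	yes
P47	Stomach	82	Woman	IIIA	1.30	no
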