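participant_id	sample_label	timepoint_class	plasma_ml	target	fpr_percent	total_cfdna_copies_per_ml	vaf_ddpcr_percent	vaf_panel_percent	ci_overlap	result_variant	result_patient	panel_result
P28	Diagnostic	diagnostic	3	TP53 p.R273H	0.03	1051	0.5	0.4	no	positive	positive	positive
P28	Diagnostic	diagnostic	3	KRAS p.G13D	0.03	1051	0.5	0.3	no	positive	positive	positive
P28	Post-surgery	post_surgery	3	TP53 p.R273H	0.03	1958	0	0	no	negative	negative	negative
P28	Post-surgery	post_surgery	3	KRAS p.G13D	0.03	1958	0.03	0	yes	negative	negative	negative
P28	Follow-up-1	follow_up	3	TP53 p.R273H	0.03	456	0	NA	no	negative	negative	NA
P28	Follow-up-1	follow_up	3	KRAS p.G13D	0.03	456	0	NA	no	negative	negative	NA
P28	Follow-up-2	follow_up	5	TP53 p.R273H	0.03	1002	0	NA	no	negative	negative	NA
P28	Follow-up-2	follow_up	5	KRAS p.G13D	0.03	1002	0	NA	no	negative	negative	NA
P27	Diagnostic	diagnostic	5	PIK3CA p.H1047R	0	8151	0.01	0	no	positive	positive	negative
P27	Diagnostic	diagnostic	5	TP53 p.R273C	0.05	8151	1.32	0.6	no	positive	positive	negative
P27	Post-surgery	post_surgery	3	PIK3CA p.H1047R	0	27247	0.006	0	no	negative	positive	negative
P27	Post-surgery	post_surgery	3	TP53 p.R273C	0.05	27247	0.1	0	no	positive	positive	negative
P27	Follow-up-1	follow_up	3	PIK3CA p.H1047R	0	1156	0	NA	no	negative	negative	NA
P27	Follow-up-1	follow_up	3	TP53 p.R273C	0.05	1156	0	NA	no	negative	negative	NA
P43	Diagnostic	diagnostic	4	KRAS p.G12D	0.06	2154	0.32	0.5	no	positive	positive	positive
P43	Post-surgery	post_surgery	3	KRAS p.G12D	0.06	5348	0.24	0	no	positive	positive	negative
P43	Follow-up-1	follow_up	5	KRAS p.G12D	0.06	2183	0.6	NA	no	positive	positive	NA
P38	Diagnostic	diagnostic	4	TP53 p.R248W	0.01	1119	0.19	0.3	no	positive	positive	positive
P38	Post-surgery	post_surgery	5	TP53 p.R248W	0.01	7111	0.01	0	no	negative	negative	negative
P41	Diagnostic	diagnostic	4	RB1 p.R358*	0.04	933	14.7	0	no	positive	positive	negative
P41	Diagnostic	diagnostic	4	TP53 p.R273C	0.03	933	6.8	17	no	positive	positive	positive
P41	Post-surgery	post_surgery	4	RB1 p.R358*	0.04	28862	0.17	0	no	positive	positive	negative
P41	Post-surgery	post_surgery	4	TP53 p.R273C	0.03	28862	0.27	0	no	positive	positive	negative
P41	Follow-up-1	follow_up	4	RB1 p.R358*	0.04	1376	3.15	NA	no	positive	positive	NA
P41	Follow-up-1	follow_up	4	TP53 p.R273C	0.03	1376	1.42	NA	no	positive	positive	NA
P25	Diagnostic	diagnostic	4	TP53 p.R196*	0.02	5080	0.02	0.07	no	negative	negative	positive
P25	Post-surgery	post_surgery	3	TP53 p.R196*	0.02	131322	0.0003	0	no	negative	negative	negative
P25	Follow-up-1	follow_up	3	TP53 p.R196*	0.02	1898	0.02	NA	no	negative	negative	NA
P25	Follow-up-2	follow_up	3	TP53 p.R196*	0.02	2928	0.3	NA	no	positive	positive	NA
P12	Diagnostic	diagnostic	3	APC p.R823*	0.04	3597	0.59	0.7	no	positive	positive	positive
P12	Diagnostic	diagnostic	3	TP53 c.720_766del	0	3597	0.98	0.3	no	positive	positive	positive
P12	Chemo-follow1	chemo_follow	3	APC p.R823*	0.04	2776	0	NA	no	negative	negative	NA
P12	Chemo-follow1	chemo_follow	3	TP53 c.720_766del	0	2776	0	NA	no	negative	negative	NA
P12	Chemo-follow2	chemo_follow	3	APC p.R823*	0.04	2180	0	NA	no	negative	negative	NA
P12	Chemo-follow2	chemo_follow	3	TP53 c.720_766del	0	2180	0	NA	no	negative	negative	NA
P12	Chemo-follow3	chemo_follow	3	APC p.R823*	0.04	897	0	NA	no	negative	negative	NA
P12	Chemo-follow3	chemo_follow	3	TP53 c.720_766del	0	897	0	NA	no	negative	negative	NA
P12	Chemo-follow4	chemo_follow	3	APC p.R823*	0.04	2748	0.16	NA	no	positive	positive	NA
P12	Chemo-follow4	chemo_follow	3	TP53 c.720_766del	0	2748	0.68	NA	no	positive	positive	NA
P12	Post-surgery	post_surgery	3	APC p.R823*	0.04	12596	0.02	0	no	negative	negative	negative
P12	Post-surgery	post_surgery	3	TP53 c.720_766del	0	12596	0	0	no	negative	negative	negative
P15	Diagnostic	diagnostic	3	TP53 p.R248Q	0.04	10437	0.27	0.23	no	positive	positive	positive
P15	Diagnostic	diagnostic	3	ERBB2 p.S310Y	0	10437	0.19	0	no	positive	positive	negative
P15	Post-surgery	post_surgery	3	TP53 p.R248Q	0.04	13968	0.04	0	no	negative	positive	negative
P15	Post-surgery	post_surgery	3	ERBB2 p.S310Y	0	13968	0.01	0	no	positive	positive	negative
P15	Follow-up-1	follow_up	3	TP53 p.R248Q	0.04	7323	3.71	NA	no	positive	positive	NA
P15	Follow-up-1	follow_up	3	ERBB2 p.S310Y	0	7323	4.0	NA	no	positive	positive	NA
P44	Diagnostic	diagnostic	3	TP53 p.R273H	0.03	576	0.25	0.26	yes	negative	negative	positive
P44	Diagnostic	diagnostic	3	KRAS p.G13D	0.03	576	0	0	no	negative	negative	negative
P44	Post-surgery	post_surgery	4	TP53 p.R273H	0.03	4879	0.1	0	no	positive	positive	negative
P44	Post-surgery	post_surgery	4	KRAS p.G13D	0.03	4879	0.07	0	no	positive	positive	negative
P42	Diagnostic	diagnostic	4	TP53 p.R158fs*12	0.02	5721	0.006	0	no	negative	negative	NA
P42	Post-surgery	post_surgery	4	TP53 p.R158fs*12	0.02	38515	0	0	no	negative	negative	negative
P32	Diagnostic	diagnostic	4	TP53 p.R248W	0.02	2455	0	0	no	negative	negative	negative
P32	Post-surgery	post_surgery	5	TP53 p.R248W	0.02	100726	0.04	0	no	positive	positive	negative
P32	Follow-up-1	follow_up	3	TP53 p.R248W	0.02	1227	0	NA	no	negative	negative	NA
P32	Follow-up-2	follow_up	5	TP53 p.R248W	0.02	1944	0	NA	no	negative	negative	NA
P23	Diagnostic	diagnostic	4	TP53 p.R273H	0.03	560	0	0	no	negative	negative	negative
P23	Diagnostic	diagnostic	4	KRAS p.G13D	0.03	560	0.2	0	yes	negative	negative	negative
P23	Pre-surgery-2	pre_surgery	4	TP53 p.R273H	0.03	1054	0	NA	no	negative	negative	NA
P23	Pre-surgery-2	pre_surgery	4	KRAS p.G13D	0.03	1054	0	NA	no	negative	negative	NA
P23	Post-surgery	post_surgery	3	TP53 p.R273H	0.03	542312	0	0	no	negative	negative	negative
P23	Post-surgery	post_surgery	3	KRAS p.G13D	0.03	542312	0	0	no	negative	negative	negative
P23	Follow-up-1	follow_up	3	TP53 p.R273H	0.03	8043	0.01	NA	no	negative	negative	NA
P23	Follow-up-1	follow_up	3	KRAS p.G13D	0.03	8043	0.03	NA	no	negative	negative	NA
P23	Follow-up-2	follow_up	3	TP53 p.R273H	0.03	766	0	NA	no	negative	negative	NA
P23	Follow-up-2	follow_up	3	KRAS p.G13D	0.03	766	0	NA	no	negative	negative	NA
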