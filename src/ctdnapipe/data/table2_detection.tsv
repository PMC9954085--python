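participant_id	expected_variants	off_panel	a_diagnostic	b_diagnostic	c_diagnostic	d_diagnostic	a_post	b_post	c_post	d_post	plasma_diagnostic_ng	plasma_diagnostic_ml	plasma_post_ng	plasma_post_ml
P01	N	no	0	0	1	1	0	0	0	0	36.9	5	21.2	3
P02	Y	no	1	1	2	1	0	0	0	0	17.9	3	8.5	2
P03	Y	no	0	0	0	0	0	0	0	0	26.3	4	28.3	3
P04	N	no	0	0	4	4	0	0	0	0	42.9	4	54.5	2
P05	Y	no	9	9	10	7	4	4	4	1	73.5	5	206	3
P06	N	no	0	0	0	0	0	0	1	1	250	5	75	3
P07	Y	no	1	1	2	2	0	0	0	0	33.3	3	60	3
P08	Y	no	2	2	4	4	0	0	0	0	26.3	3	81	4
P09	N	no	0	0	1	1	0	0	0	0	68	3	69	5
P10	Y	no	0	0	0	0	0	0	1	1	25.5	5	32.2	3
P11	Y	no	0	0	0	0	0	0	0	0	45.9	2	139	3
P12	Y	no	3	3	4	4	0	0	0	0	81.5	3	247	3
P13	N	no	0	0	0	0	0	0	0	0	66	5	250	4
P14	N	no	0	0	0	0	0	0	0	0	110	5	250	3
P15	Y	no	2	2	2	2	0	0	0	0	236	5	250	3
P16	N	no	0	0	2	1	0	0	1	0	39.3	5	231	3
P17	Y	no	3	3	4	3	2	2	2	2	26.7	4	68.5	3
P18	Y	no	15	15	15	15	0	0	0	0	17.6	4	28.4	4
P19	Y	no	0	0	0	0	0	0	0	0	189	5	47	4
P20	N	no	0	0	0	0	0	0	0	0	47	5	250	3
P21	Y	no	0	1	0	0	0	0	0	0	55.5	5	250	3
P22	Y	no	0	0	0	0	0	0	0	0	39.2	5	29	3
P23	Y	no	0	0	1	1	0	0	0	0	20.8	4	250	3
P24	Y	no	0	0	0	0	0	1	0	0	134	5	158	3
P25	Y	no	1	0	1	1	0	0	0	0	48.6	4	250	3
P26	Y	no	0	0	0	0	1	0	1	1	16.8	4	141	3
P27	Y	no	1	1	3	1	0	0	0	0	222	5	250	4
P28	Y	no	3	3	3	3	0	0	0	0	52.5	3	155	3
P29	Y	no	0	0	0	0	0	0	0	0	106	3	197	3
P30	Y	no	2	2	3	3	0	0	0	0	19.2	4	72.5	3
P31	N	no	0	0	1	1	0	0	0	0	24.6	3	250	5
P32	Y	no	0	0	0	0	0	0	0	0	71.5	4	250	4
P33	Y	no	0	0	2	0	NA	NA	NA	NA	116	4	NA	4
P34	N	no	0	0	0	0	0	0	0	0	35.8	4	120	3
P35	N	no	0	0	0	0	0	0	0	0	96	4	149	4
P36	N	no	NA	NA	NA	NA	0	0	0	NA	NA	4	241	4
P37	Y	yes	0	0	0	0	0	0	0	0	65	4	250	4
P38	Y	no	1	1	2	NA	NA	NA	NA	NA	24	4	NA	4
P39	N	no	0	0	1	1	0	0	0	0	11.1	3	168	4
P40	Y	no	0	0	0	0	0	0	0	0	38.7	4	250	4
P41	Y	no	1	1	2	2	0	0	0	0	47	4	250	4
P42	Y	no	NA	NA	NA	NA	0	0	0	NA	NA	4	250	4
P43	Y	no	3	4	4	2	1	1	2	0	98.5	4	250	4
P44	Y	no	0	1	1	0	0	0	1	0	125	4	250	4
P45	N	no	NA	NA	NA	NA	0	0	0	NA	NA	NA	55	3
P46	N	no	0	0	1	1	0	0	0	0	33	3	250	4
P47	Y	no	1	1	1	1	0	0	0	0	51.5	4	250	4
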