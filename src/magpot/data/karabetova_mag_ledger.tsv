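bin_id	domain	taxon	completeness_pct	contamination_pct	n_contigs	genome_size_mbp	s16_length_bp	abundance_pct
KA1	B	"Cloacimonadales"	100	0.00	52	2.39	1564	0.52
KA2	A	ANME-2a (HR1)	100	1.96	70	2.40	1470	1.72
KA3	B	Mariniphaga	98.92	3.23	305	5.12	1528	0.91
KA4	B	"Syntrophosphaera"	98.90	0.00	134	2.38	1553	0.45
KA5	B	Desulfocapsaceae	98.71	0.60	72	2.84	-	1.41
KA6	B	Desulfuromonadaceae	98.71	1.94	64	2.90	620	1.19
KA7	B	Desulfobacterota	98.32	0.84	54	2.62	1576	3.73
KA8	B	Geopsychrobacteraceae	98.06	0.65	61	2.75	686	1.71
KA9	B	Phaeovulum	97.88	1.06	69	2.86	-	0.75
KA10	B	Bacteroidales (VadinHA17)	97.86	3.35	263	3.39	403	0.41
KA11	B	Sulfurimonas	97.35	1.90	73	2.06	303	3.74
KA12	B	Lentimicrobium	97.31	1.61	108	4.19	-	0.98
KA13	B	Bacteroidales	97.22	1.61	224	3.57	-	0.96
KA14	B	Syntrophales	96.77	0.65	95	3.10	1569	1.34
KA15	B	Burkholderiaceae	96.30	3.47	509	3.72	1534	0.41
KA16	B	"Thiohalomonadaceae"	96.07	1.35	162	2.41	1420	0.46
KA17	B	Vicingaceae	95.16	0.54	232	3.66	1524	0.57
KA18	B	Coriobacteria (OPB41)	93.47	3.61	143	2.07	1523	1.36
KA19	A	ANME-3	92.81	0.65	275	1.80	1480	30.32
KA20	B	Anaerolineaceae	92.55	4.73	368	4.20	283	0.40
KA21	B	Bacteroidales	91.64	1.63	239	2.89	260	0.38
KA22	B	"Dethiobacteria"	90.25	2.26	170	2.36	-	0.43
KA23	B	"Brevefilum"	90.00	4.73	149	3.05	1525	1.20
KA24	A	Archaea EX4484-52	88.79	1.87	33	1.16	1468	2.10
KA25	B	Bacteroidales	88.17	2.96	382	4.18	-	0.51
KA26	B	Trueperaceae	87.92	1.55	389	3.29	1521	0.70
KA27	A	Archaea EX4484-52	85.98	1.87	20	1.08	1471	8.88
KA28	B	"Marinisomatota"	76.03	1.65	356	1.32	452	0.28
KA29	B	Methyloprofundus	73.30	1.92	384	1.96	-	0.28
KA30	B	"Patescibacteria" (WWE3)	73.12	0.16	71	0.84	497	0.37
KA31	B	"Pacebacteria"	71.24	1.12	52	0.98	1471	13.32
KA32	A	"Pacearchaeales"	69.39	0.00	9	0.64	1449	0.79
KA33	B	"Patescibacteria" (CPR2)	51.88	0.00	146	0.50	-	0.27
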