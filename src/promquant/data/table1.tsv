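gene_id	gene_name	operon	function	array_log2	rnaseq_log2	proteomics_log2	ratio_log_phase	sd_log_phase	ratio_stationary	sd_stationary	strength_class
ZMO0177	gap		Glyceraldehyde-3-phosphate dehydrogenase, type I	15.06	11.2	9.23	0.38	0.0202	0.47	0.0191	strong
ZMO1360	pdc		Thiamine pyrophosphate protein TPP binding domain-containing protein	14.52	11.78	8.59	0.24	0.0220	0.22	0.0086	strong
ZMO0516	Tuf	ND	Elongation factor Tu	15.33	11.58	8.08	0.24	0.0162	0.30	0.0148	strong
ZMO1608	eno		Phosphopyruvate hydratase	15.22	13.2	8.97	0.23	0.0145	0.34	0.0093	strong
ZMO0997	eda	Yes	2-Dehydro-3-deoxyphosphogluconate aldolase/4-hydroxy-2-oxoglutarate aldolase	14.97	14.6	8.46	0.18	0.0178	0.15	0.0167	strong
ZMO0367	zwf		Glucose-6-phosphate 1-dehydrogenase	14.92	11.19	7.38	0.16	0.0057	0.14	0.0124	strong
ZMO1719	frk		ROK family protein	15.06	12.2	6.85	0.12	0.0038	0.17	0.0098	strong
ZMO1609			Hypothetical protein	15.26	12.77	5.78	0.12	0.0061	0.14	0.0038	strong
ZMO0689	gfo		Oxidoreductase domain-containing protein	14.49	11.68	6.38	0.10	0.0075	0.13	0.0130	strong
ZMO1721	gloA3	ND	Glyoxalase/bleomycin resistance protein/dioxygenase	14.35	12.66	5.97	0.09	0.0044	0.11	0.0022	strong
ZMO0514	rpsG	Yes	30S ribosomal protein S7	15.31	10.79	5.54	0.07	0.0062	0.07	0.0015	strong
ZMO0515		Yes	Elongation factor G	15.07	11.14	5.83	0.07	0.0062	0.07	0.0015	strong
ZMO1596	adhB		Iron-containing alcohol dehydrogenase	15.32	10.98	7.07	0.07	0.0084	0.07	0.0030	strong
ZMO1141	ilvC	Yes	Ketol-acid reductoisomerase	15.41	12.39	6.76	0.05	0.0012	0.04	0.0006	strong
ZMO0241	atpD	Yes	F0F1 ATP synthase subunit beta	15.09	11.73	7.77	0.05	0.0030	0.04	0.0029	strong
ZMO0244			Histone family protein DNA-binding protein	14.79	12.98	6.1	0.04	0.0013	0.04	0.0007	strong
Po1721							0.04	0.0020	0.03	0.0007	strong
ZMO0493	glnA	Yes	Glutamine synthetase, type I	14.53	10.02	6.17	0.03	0.0023	0.03	0.0005	strong
ZMO1779		Yes	Antibiotic biosynthesis monooxygenase	15.08	11.24	7.52	0.02	0.0005	0.02	0.0008	strong
ZMO1351	clcD1	Yes	Carboxymethylenebutenolidase	12.93	6.81	3.14	0.14	0.0064	0.16	0.0036	medium
ZMO0056	glmS		Glucosamine-fructose-6-phosphate aminotransferase	12.93	6.91	2.45	0.12	0.0021	0.11	0.0024	medium
ZMO0559			Hypothetical protein	12.68	6.75	3.1	0.11	0.0064	0.08	0.0039	medium
ZMO1385			Toxic anion resistance family protein	12.83	6.93	2.55	0.06	0.0012	0.05	0.0018	medium
ZMO0127		Yes	S1/P1 nuclease	12.84	7.11	3.13	0.05	0.0015	0.05	0.0014	medium
ZMO1100		Yes	Nucleotidyl transferase	12.58	7.18	2.82	0.05	0.0012	0.05	0.0023	medium
ZMO1392			Hypothetical protein	12.46	7.43	2.45	0.04	0.0012	0.04	0.0012	medium
ZMO0326			7-cyano-7-deazaguanine reductase	12.65	7.41	2.7	0.03	0.0018	0.04	0.0012	medium
ZMO0570	prmA		Ribosomal L11 methyltransferase	12.38	7.32	2.45	0.03	0.0030	0.04	0.0013	medium
ZMO1231	recJ		Single-stranded-DNA-specific exonuclease RecJ	11.03	5.7	0.07	0.08	0.0023	0.07	0.0029	weak
ZMO1980	gidB	Yes	Methyltransferase GidB	10.59	5.27	0.07	0.05	0.0025	0.05	0.0029	weak
ZMO1484			UvrD/REP helicase	10.93	5.4	0.07	0.05	0.0013	0.05	0.0026	weak
ZMO0145		Yes	Peptidase M28	11.37	4.98	0.07	0.04	0.0018	0.04	0.0006	weak
ZMO0101			NAD-dependent epimerase/dehydratase	10.61	5.05	0.07	0.04	0.0013	0.04	0.0014	weak
ZMO1194	dprA	Yes	DNA protecting protein DprA	10.7	4.77	0.07	0.04	0.0011	0.03	0.0006	weak
ZMO1644			DEAD/DEAH box helicase domain-containing protein	10.61	4.98	0.07	0.03	0.0013	0.03	0.0007	weak
ZMO1582			Uracil-DNA glycosylase superfamily protein	10.33	4.63	0.07	0.03	0.0004	0.03	0.0003	weak
ZMO0005	cysD	Yes	Sulfate adenylyltransferase subunit 2	11.5	5.28	0.07	0.03	0.0012	0.03	0.0009	weak
ZMO0300	xseA		Exodeoxyribonuclease VII large subunit	11.6	4.71	0.07	0.03	0.0010	0.03	0.0013	weak
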