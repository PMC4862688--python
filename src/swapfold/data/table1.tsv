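protein	K	RCO	dG_f	dG_s	population	provenance
SH3	0	0.33	2.7	9.2	95.7	paper-fixture
SH3	18	0.38	3.4	2.5	1.1	paper-fixture
SH3	37	0.37	4.1	4.8	2.2	paper-fixture
SH3	46	0.35	3.0	5.2	1.1	paper-fixture
PDZ	0	0.32	2.5	4.5	88.7	paper-fixture
PDZ	10	0.28	2.5	2.4	6.7	paper-fixture
PDZ	23	0.33	3.6	1.6	2.3	paper-fixture
PDZ	43	0.27	2.8	0.3	1.7	paper-fixture
PDZ	60	0.33	4.2	0.3	0.7	paper-fixture
PDZ	74	0.26	3.7	0.3	0.0	paper-fixture
TNfn3	0	0.32	2.4	8.1	89.2	paper-fixture
TNfn3	16	0.33	2.4	1.6	0.0	paper-fixture
TNfn3	28	0.27	3.4	2.8	0.9	paper-fixture
TNfn3	43	0.34	3.9	1.8	2.3	paper-fixture
TNfn3	54	0.29	3.7	1.1	0.6	paper-fixture
TNfn3	66	0.27	3.5	1.8	1.3	paper-fixture
TNfn3	79	0.35	2.5	2.5	5.7	paper-fixture
UBQ	0	0.29	2.5	4.2	100.0	paper-fixture
UBQ	9	0.29	3.1	-2.9	0.0	paper-fixture
UBQ	21	0.28	2.7	-3.2	0.0	paper-fixture
UBQ	36	0.28	6.3	-6.3	0.0	paper-fixture
UBQ	61	0.26	3.5	-3.3	0.0	paper-fixture
SH2	0	0.24	2.6	6.1	91.7	paper-fixture
SH2	11	0.25	3.1	3.1	0.4	paper-fixture
SH2	24	0.30	3.2	1.8	0.0	paper-fixture
SH2	37	0.28	2.7	3.3	0.9	paper-fixture
SH2	49	0.25	3.3	3.2	1.1	paper-fixture
SH2	61	0.26	3.8	3.5	2.8	paper-fixture
SH2	72	0.27	3.9	2.5	2.6	paper-fixture
SH2	89	0.26	3.2	2.0	0.4	paper-fixture
TitinI27	0	0.34	2.5	8.1	92.0	paper-fixture
TitinI27	16	0.36	3.0	1.5	0.3	paper-fixture
TitinI27	28	0.30	2.8	3.0	3.1	paper-fixture
TitinI27	37	0.33	2.8	2.9	2.9	paper-fixture
TitinI27	53	0.36	3.0	2.0	0.2	paper-fixture
TitinI27	64	0.30	3.0	1.0	0.4	paper-fixture
TitinI27	76	0.33	2.8	2.3	2.0	paper-fixture
GB1	0	0.35	2.5	3.1	100.0	paper-fixture
GB1	12	0.36	4.4	-5.2	0.0	paper-fixture
GB1	23	0.31	4.6	-5.3	0.0	paper-fixture
GB1	41	0.27	4.9	-5.4	0.0	paper-fixture
GB1	50	0.36	5.3	-5.7	0.0	paper-fixture
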