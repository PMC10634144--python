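mirna	transcript	gene	tstart	tstop	tslice	mirna_log2fc	mirna_regulation	target_log2fc	target_regulation
ghr-MIR156d-p3	Ghir_D01G014780.1	PERK12	1778	1798	1790	-1.32	down	5.00	up
ghr-miR164	Ghir_A07G023180.1	Ghir_A07G023180	591	613	603	3.02	up	-2.39	down
ghr-MIR169b-p3_1ss6AG	Ghir_A01G016050.1	BGAL13	1181	1203	1191	-1.69	down	6.32	up
ghr-MIR169b-p3_1ss6AG	Ghir_A04G005510.1	DDB_G0282179	598	619	610	-1.69	down	4.58	up
ghr-miR390a	Ghir_A11G033170.1	LIP1	1082	1102	1093	0.95	up	-3.55	down
ghr-miR390a	Ghir_A13G022220.2	Bp10	119	138	130	0.95	up	-2.21	down
ghr-miR390a	Ghir_D08G026350.1	GLOX1	1493	1514	1504	2.89	up	-2.74	down
ghr-MIR390b-p3	Ghir_D11G021420.3	BT4	1111	1132	1123	1.00	up	-15.19	down
ghr-miR7505	Ghir_A01G016050.1	BGAL13	1857	1878	1869	-0.62	down	6.32	up
ghr-MIR7508-p3	Ghir_A03G000550.1	Ghir_A03G000550	1060	1083	1073	-1.26	down	5.92	up
ghr-MIR7508-p3	Ghir_A08G009550.1	Ghir_A08G009550	1030	1050	1041	-1.26	down	16.02	up
ghr-MIR7508-p3	Ghir_A11G003080.1	Ghir_A11G003080	1155	1177	1168	-1.26	down	4.27	up
ghr-MIR7508-p3	Ghir_D13G011540.1	CCR4	803	828	818	-1.26	down	4.90	up
gra-miR482_L-2R + 2	Ghir_D11G002690.7	ORP2A	168	190	180	1.01	up	-3.25	down
gra-MIR7494c-p3_2ss17TC20TC	Ghir_A01G007270.1	Ghir_A01G007270	537	561	550	-1.37	down	4.46	up
gra-MIR7494c-p3_2ss17TC20TC	Ghir_D05G016260.1	E6	990	1012	1003	-1.37	down	4.84	up
gra-MIR8643a-p3	Ghir_A01G007270.1	Ghir_A01G007270	691	711	702	-1.63	down	4.46	up
gra-MIR8643a-p3	Ghir_D01G007580.1	Ghir_D01G007580	678	698	689	-1.63	down	3.71	up
gra-MIR8643a-p3	Ghir_D03G003510.1	RBK1	424	441	432	-1.63	down	5.37	up
gra-MIR8643a-p3	Ghir_D12G025940.1	OMT	610	631	622	-1.63	down	3.01	up
gra-MIR8741-p3	Ghir_A03G003770.2	ABCF1	752	772	763	-0.61	down	14.08	up
lja-miR171d-5p	Ghir_A03G019420.1	PUMP4	796	821	812	-1.81	down	3.33	up
lja-miR171d-5p	Ghir_D02G020840.1	PUMP4	607	632	623	-1.81	down	6.17	up
mtr-miR159a	Ghir_D05G010040.3	SE	2843	2862	2853	3.83	up	-7.05	down
mtr-miR167a_R + 1	Ghir_A07G018870.1	ARF8	2856	2877	2868	4.41	up	-6.67	down
PC-3p-4246_1488	Ghir_A03G022040.1	Ghir_A03G022040	871	894	883	-0.94	down	3.18	up
PC-5p-22518_209	Ghir_A08G021530.1	Ghir_A08G021530	2222	2242	2233	-0.54	down	5.12	up
PC-5p-27836_155	Ghir_D05G011000.2	SKOR	2235	2255	2246	3.50	up	-6.60	down
PC-5p-40123_91	Ghir_D05G038130.1	Ghir_D05G038130	242	265	256	-inf	down	3.46	up
PC-5p-4140_1526	Ghir_A01G016050.1	BGAL13	1216	1236	1227	-2.17	down	6.32	up
PC-5p-4140_1526	Ghir_A08G025450.1	GLOX1	1079	1101	1090	-2.17	down	3.63	up
ptc-miR319a	Ghir_A12G004340.3	SFH3	904	923	913	2.33	up	-3.59	down
tcc-miR167c	Ghir_A13G022250.1	Bp10	429	449	440	1.21	up	-8.57	down
tcc-miR396c	Ghir_A04G002210.3	FH5	2631	2651	2642	3.00	up	-3.94	down
tcc-miR396c_L-1	Ghir_A09G001320.1	PME31	593	613	604	inf	up	-2.69	down
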