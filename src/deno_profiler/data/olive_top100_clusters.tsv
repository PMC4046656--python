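# The 100 most abundant/significant unigenes of the olive (Olea europaea cv. Picual)
# ripe-fruit pericarp vs abscission-zone comparison at 217 DPA, with normalized
# abundance (RPKM x1000) per tissue, exact-test p-value, and published cluster label
# (A1 fruit-enriched, A2 fruit-exclusive, B1 AZ-enriched, B2 AZ-exclusive; 25 each).
# An abundance printed as exactly 0.00 denotes zero raw reads in that tissue.
unigene	uniprot	rpkm1000_fruit	rpkm1000_az	pvalue	label	description
OL006944	Q2TUW1	20742.30	1196.08	0.0	A1	Abscisic stress ripening-like protein
OL007219	Q8GVD0	5033.88	214.76	0.0	A1	Beta-glucosidase, Bglc
OL001156	B9H1F2	5022.65	95.79	0.0	A1	Uncharacterized protein
OL006467	E0CU96	2920.45	169.91	0.0	A1	Uncharacterized protein
OL001418	B9R8J3	8902.90	1040.58	0.0	A1	Phosphoprotein ECPP44
OL007236	Q8H159	4247.26	1430.34	0.0	A1	Polyubiquitin 10
OL003644	C6KMJ4	4794.95	1423.76	0.0	A1	ACC oxidase, ACO1
OL006886	Q0WLP3	5085.83	870.26	0.0	A1	Uncharacterized protein
OL006727	P29512	1812.59	180.74	0.0	A1	Tubulin beta-2/beta-3 chain
OL006856	Q06R56	1174.95	18.56	0.0	A1	Acetyl-CoA carboxylase beta subunit accD
OL006553	O04111	1437.34	5.97	0.0	A1	Chalcone synthase, CHS
OL002387	B9S382	949.24	22.02	0.0	A1	Tubulin beta chain
OL000027	A2IBF9	1329.71	22.64	0.0	A1	Flavanone-3-hydroxylase
OL002907	B9SLE5	3731.27	15.50	0.0	A1	Peptidase
OL000014	A1E4D3	610.81	13.51	0.0	A1	Ethylene receptor, ETR1
OL003708	D5LY28	609.68	3.53	0.0	A1	Soluble acid invertase 1, SAI1
OL001944	B9RP00	1995.12	42.28	9.70e-301	A1	Uncharacterized protein
OL007516	Q9LLB7	4587.02	1203.54	5.39e-270	A1	Thaumatin-like protein
OL001075	B7U8J4	1418.63	52.49	1.22e-244	A1	Expansin, CDK3
OL005738	D7U0E8	538.58	14.77	2.73e-233	A1	Uncharacterized protein
OL007398	Q9AXU0	1854.70	19.23	5.46e-226	A1	Major latex-like protein
OL000584	A5BN70	585.33	8.71	2.72e-204	A1	Uncharacterized protein
OL006621	O49877	1057.22	162.37	2.53e-201	A1	CYP1 (Cysteine protease TDI-65)
OL004008	D7SNI5	615.01	5.64	2.08e-200	A1	Uncharacterized protein
OL007235	Q8H145	432.58	14.77	5.11e-200	A1	Putative elongation factor (Fragment)
OL003887	D7SKG3	9684.90	0.00	0.0	A2	Uncharacterized protein
OL004525	D7T2N4	5878.45	0.00	0.0	A2	6,7-dimethyl-8-ribityllumazine synthase
OL000028	A2ICC9	2823.47	0.00	0.0	A2	Anthocyanidin synthase, ANS
OL006333	E0CQN9	1291.93	0.00	0.0	A2	Uncharacterized protein
OL002413	B9S4E4	2111.11	0.00	0.0	A2	Alpha-expansin 8
OL004078	D7SQ46	928.57	0.00	0.0	A2	Uncharacterized protein
OL002282	B9S053	1262.49	0.00	0.0	A2	ATP synthase alpha subunit mitochondrial
OL003892	D7SKJ8	1091.87	0.00	0.0	A2	Uncharacterized protein
OL004267	D7SVD2	1810.56	0.00	5.65e-279	A2	Uncharacterized protein
OL006945	Q2UYU6	619.52	0.00	3.12e-265	A2	Flavonoid-3'-hydroxylase
OL003801	D7SI22	693.27	0.00	7.63e-263	A2	Uncharacterized protein
OL005180	D7TJ49	903.07	0.00	2.23e-255	A2	Uncharacterized protein
OL007481	Q9FXL4	642.40	0.00	8.53e-252	A2	Elicitor inducible beta-1,3-glucanase, NtEIG-E76
OL004529	D7T2X5	1244.84	0.00	2.22e-235	A2	Uncharacterized protein
OL004452	D7T0N0	444.07	0.00	1.16e-219	A2	Uncharacterized protein
OL001743	B9RI89	699.45	0.00	1.76e-215	A2	Serine-threonine protein kinase
OL007506	Q9LIC2	398.86	0.00	3.50e-215	A2	Multispanning membrane protein-like
OL005327	D7TN33	2085.55	0.00	7.29e-198	A2	Uncharacterized protein
OL004599	D7T4I1	790.51	0.00	5.34e-191	A2	Uncharacterized protein
OL007004	Q40168	880.38	0.00	1.21e-182	A2	Floral homeotic protein AGAMOUS, TAG1
OL001261	B9I6M7	505.91	0.00	2.94e-181	A2	Uncharacterized protein
OL007205	Q84V57	368.45	0.00	1.16e-180	A2	Pectinesterase
OL006690	P14721	454.41	0.00	4.27e-171	A2	Dihydroflavonol-4-reductase, DFRA
OL006603	O24329	532.05	0.00	2.50e-163	A2	Putative uncharacterized protein
OL007050	Q45QI7	831.88	0.00	3.09e-161	A2	Chalcone-flavonone isomerase, CHI
OL007063	Q53U35	466.67	39974.19	0.0	B1	Similar to pathogenesis-related protein, STH-2
OL004910	D7TBW7	92.31	12814.10	0.0	B1	Uncharacterized protein
OL000784	A5C4X8	19.48	1499.53	0.0	B1	Uncharacterized protein
OL005534	D7TTS3	9.40	677.78	7.69e-234	B1	Uncharacterized protein
OL001130	B9GQM0	24.67	528.28	1.89e-222	B1	Glycosyltransferase, CAZy family GT8
OL001048	B3Y023	6.44	337.01	1.24e-210	B1	Arginine decarboxylase, PpADC
OL001934	B9RNU7	144.97	1060.02	1.01e-205	B1	Protein phosphatase 2c
OL007508	Q9LJU7	141.11	842.87	6.39e-178	B1	Purple acid phosphatase 18, PAP18
OL000621	A5BSF5	14.55	385.83	8.80e-161	B1	Uncharacterized protein
OL004617	D7T4X3	86.61	712.16	3.01e-154	B1	Uncharacterized protein
OL000020	A1X877	6.01	209.08	1.26e-152	B1	NRC1
OL002350	B9S255	11.95	656.04	2.81e-144	B1	Uncharacterized protein
OL002844	B9SJN1	4.75	235.99	1.57e-143	B1	Transcription factor hy5
OL000814	A5C762	3.65	376.25	2.47e-126	B1	Uncharacterized protein
OL003935	D7SLN3	4.44	211.35	3.03e-122	B1	Uncharacterized protein
OL003232	B9SWQ3	15.25	265.80	2.37e-119	B1	Serine/threonine protein kinase
OL000971	A9PCV7	6.58	498.02	7.68e-114	B1	Uncharacterized protein
OL004147	D7SS09	8.28	365.56	8.33e-113	B1	Uncharacterized protein
OL003339	B9T0K9	6.41	353.47	1.06e-112	B1	Plasminogen activator inhibitor 1 RNA-binding protein, putative
OL007507	Q9LJI5	50.33	494.78	6.20e-107	B1	V-type proton ATPase subunit d1, VHA-D1
OL000585	A5BN72	2.24	113.57	6.46e-103	B1	Uncharacterized protein
OL001014	B1PK08	114.23	616.10	3.23e-100	B1	Putative polygalacturonase
OL007154	Q6RYA0	51.28	584.61	1.32e-98	B1	Salicylic acid-binding protein 2
OL003709	D5M8I6	22.52	216.21	3.46e-98	B1	Uncharacterized protein
OL000614	A5BR22	108.46	1156.08	1.18e-92	B1	Uncharacterized protein
OL007111	Q68V46	0.00	1349.85	0.0	B2	Beta-1,3-glucanase, glu-4
OL001027	B2M153	0.00	517.74	4.51e-277	B2	Putative laccase
OL002714	B9SF95	0.00	614.34	7.75e-267	B2	Nitrate transporter
OL006675	O98664	0.00	576.60	5.46e-253	B2	Ribulose bisphosphate carboxylase large chain, rbcL
OL007711	Q9XEL8	0.00	396.80	8.65e-224	B2	3-hydroxy-3-methylglutaryl-coenzyme A reductase 2, HMGR2
OL000602	A5BPW9	0.00	602.46	2.97e-213	B2	Uncharacterized protein
OL001338	B9NAX4	0.00	3264.55	3.51e-192	B2	Uncharacterized protein
OL000148	A5AN11	0.00	396.34	1.06e-168	B2	Uncharacterized protein
OL004086	D7SQA7	0.00	273.23	1.06e-168	B2	Uncharacterized protein
OL003142	B9STR3	0.00	277.60	5.43e-166	B2	Endosomal P24A protein
OL002860	B9SK95	0.00	489.81	8.68e-165	B2	12-oxophytodienoate reductase opr
OL005126	D7THY5	0.00	222.22	1.74e-164	B2	Uncharacterized protein
OL007151	Q6RH27	0.00	570.32	1.42e-160	B2	NAC domain protein, SlNAC1
OL004686	D7T6Y2	0.00	305.72	6.41e-145	B2	Uncharacterized protein
OL007397	Q9AXR6	0.00	248.90	1.31e-141	B2	ATP:citrate lyase
OL000367	A5B7F7	0.00	319.83	2.10e-140	B2	Uncharacterized protein
OL002951	B9SML0	0.00	214.99	6.88e-136	B2	Lyase
OL007180	Q7XE16	0.00	176.98	8.81e-134	B2	Cell division cycle protein 48
OL005047	D7TFE6	0.00	357.56	1.76e-133	B2	Uncharacterized protein
OL000444	A5BDC8	0.00	382.41	5.77e-129	B2	Uncharacterized protein
OL002899	B9SL31	0.00	245.52	2.31e-128	B2	Transcription factor
OL003084	B9SRT5	0.00	96.17	1.89e-124	B2	Phospholipid-transporting atpase
OL007255	Q8LAH7	0.00	341.40	4.96e-119	B2	12-oxophytodienoate reductase 1, AtOPR1
OL001800	B9RJM7	0.00	394.51	1.27e-116	B2	Uncharacterized protein
OL002929	B9SM03	0.00	296.74	2.54e-116	B2	Uncharacterized protein
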