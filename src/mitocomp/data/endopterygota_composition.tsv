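order	n	taxon	at_cluster	at_pct	at_skew_cluster	at_skew	gc_skew_cluster	gc_skew
COL	1	Acmaeodera sp.	A1	68.41	B4	0.1142	C4	-0.2492
COL	2	Adelium sp.	A2	72.71	B4	0.1367	C4	-0.2222
COL	3	Anoplophora glabripennis	A3	78.31	B2	0.0116	C4	-0.2066
COL	4	Apatides fortis	A1	67.19	B5	0.1704	C3	-0.2946
COL	5	Chaetosoma scaritides	A3	79.04	B2	0.0427	C4	-0.2008
COL	6	Chauliognathus opacus	A3	76.86	B4	0.1120	C5	-0.1532
COL	7	Chrysochroa fulgidissima	A1	69.92	B6	0.2026	C4	-0.2373
COL	8	Crioceris duodecimpunctata	A3	76.89	B2	0.0442	C5	-0.1634
COL	9	Cyphon sp.	A3	75.17	B3	0.0721	C4	-0.2282
COL	10	Hydroscapha granulum	A3	77.29	B2	0.0297	C5	-0.1519
COL	11	Lucanus mazama	A1	67.11	B3	0.0743	C3	-0.2723
COL	12	Macrogyrus oblongus	A3	78.00	B2	0.0421	C4	-0.2080
COL	13	Mordella atrata	A2	71.94	B3	0.0691	C3	-0.2556
COL	14	Priasilpha obscura	A3	76.5	B3	0.0523	C3	-0.2646
COL	15	Psacothea hilaris	A3	76.63	B2	0.0114	C4	-0.2129
COL	16	Pyrocoelia rufa	A3	77.41	B4	0.1058	C5	-0.1584
COL	17	Pyrophorus divergens	A1	69.44	B5	0.1650	C3	-0.2915
COL	18	Rhagophthalmus lufengensis	A3	79.63	B4	0.1038	C5	-0.1959
COL	19	Rhagophthalmus ohbai	A3	79.15	B4	0.1185	C4	-0.2256
COL	20	Rhopaea magnicornis	A3	75.59	B2	0.0050	C4	-0.2380
COL	21	Sphaerius sp.	A4	80.68	B2	0.0104	C6	-0.1482
COL	22	Tetraphalerus bruchi	A1	66.99	B6	0.2477	C3	-0.2515
COL	23	Trachypachus holmbergi	A3	79.45	B2	0.0205	C5	-0.1536
COL	24	Tribolium castaneum	A2	71.68	B4	0.1091	C2	-0.3053
DIP	25	Aedes aegypti	A3	79.00	B2	0.0169	C4	-0.2109
DIP	26	Aedes albopictus	A3	79.54	B2	0.0079	C5	-0.1812
DIP	27	Anopheles gambiae	A3	77.56	B2	0.0322	C5	-0.1540
DIP	28	Anopheles quadrimaculatus A	A3	77.36	B2	0.0406	C5	-0.1814
DIP	29	Bactrocera carambolae	A2	73.55	B3	0.0656	C4	-0.2237
DIP	30	Bactrocera dorsalis	A2	73.58	B3	0.0675	C4	-0.2283
DIP	31	Bactrocera oleae	A2	72.63	B3	0.0884	C3	-0.2802
DIP	32	Bactrocera papayae	A2	73.52	B3	0.0662	C4	-0.2263
DIP	33	Bactrocera philippinensis	A2	73.63	B3	0.0656	C4	-0.2244
DIP	34	Ceratitis capitata	A3	77.48	B2	0.0211	C5	-0.1851
DIP	35	Chrysomya putoria	A3	76.70	B2	0.0204	C5	-0.1701
DIP	36	Cochliomyia hominivorax	A3	76.90	B2	0.0344	C4	-0.2067
DIP	37	Culicoides arakawae	A3	77.36	B2	0.0092	C4	-0.2369
DIP	38	Cydistomyia duplonotata	A3	77.93	B2	0.0031	C5	-0.1771
DIP	39	Dermatobia hominis	A3	77.82	B2	0.0429	C4	-0.2267
DIP	40	Drosophila littoralis	A3	76.24	B2	0.0124	C5	-0.1826
DIP	41	Drosophila mauritiana	A3	77.71	B2	0.0094	C6	-0.1348
DIP	42	Drosophila melanogaster	A4	82.16	B2	0.0167	C6	-0.1504
DIP	43	Drosophila sechellia	A3	77.57	B2	0.0092	C6	-0.1351
DIP	44	Drosophila simulans	A3	77.93	B2	0.0084	C6	-0.1352
DIP	45	Drosophila yakuba	A3	78.59	B2	0.0050	C6	-0.1364
DIP	46	Haematobia irritans	A3	79.07	B2	0.0044	C6	-0.1245
DIP	47	Lucilia sericata	A3	77.61	B2	0.0159	C5	-0.1666
DIP	48	Mayetiola destructor	A4	84.12	B3	0.0614	C6	-0.1100
DIP	49	Rhopalomyia pomum	A5	85.15	B2	0.0468	C6	-0.1230
DIP	50	Simosyrphus grandicornis	A4	80.84	B1	-0.0038	C6	-0.1328
DIP	51	Trichophthalma punctata	A2	73.96	B3	0.0912	C4	-0.2447
HYM	52	Abispa ephippium	A4	80.61	B1	-0.0186	C1	-0.3795
HYM	53	Apis mellifera ligustica	A4	84.86	B2	0.0183	C3	-0.2686
HYM	54	Bombus ignitus	A5	86.78	B2	0.0028	C3	-0.2719
HYM	55	Cephus cinctus	A4	81.95	B2	0.0343	C3	-0.2855
HYM	56	Diadegma semiclausum	A5	87.41	B2	0.0086	C5	-0.1984
HYM	57	Evania appendigaster	A3	77.77	B2	0.0267	C2	-0.3491
HYM	58	Melipona bicolor	A5	86.72	B2	0.0155	C3	-0.2511
HYM	59	Orussus occidentalis	A3	76.21	B2	0.0169	C2	-0.3076
HYM	60	Vanhornia eucnemidarum	A4	80.11	B3	0.0857	C2	-0.3282
LEP	61	Acraea issoria	A3	79.76	B1	-0.0234	C4	-0.2352
LEP	62	Adoxophyes honmai	A4	80.39	B1	-0.0010	C5	-0.1964
LEP	63	Antheraea pernyi	A4	80.16	B1	-0.0214	C4	-0.2163
LEP	64	Antheraea yamamai	A4	80.29	B1	-0.0221	C4	-0.2199
LEP	65	Artogeia melete	A3	79.78	B2	0.0121	C4	-0.2218
LEP	66	Bombyx mandarina	A4	81.68	B3	0.0547	C4	-0.2131
LEP	67	Bombyx mori	A4	81.32	B3	0.0587	C4	-0.2162
LEP	68	Coreana raphaelis	A4	82.66	B1	-0.0474	C5	-0.1578
LEP	69	Diatraea saccharalis	A4	80.02	B2	0.0213	C3	-0.2575
LEP	70	Eriogyna pyretorum	A4	80.82	B1	-0.0305	C4	-0.2047
LEP	71	Lymantria dispar	A3	79.88	B2	0.0160	C4	-0.2473
LEP	72	Manduca sexta	A4	81.79	B1	-0.0053	C5	-0.1811
LEP	73	Ochrogaster lunifer	A3	77.84	B2	0.0301	C2	-0.3175
LEP	74	Phthonandria atrilineata	A4	81.02	B2	0.0066	C5	-0.1921
LEP	75	Saturnia boisduvalii	A4	80.62	B1	-0.0240	C4	-0.2170
NEU	76	Ascaloptynx appendiculatus	A3	75.57	B3	0.0676	C4	-0.2059
NEU	77	Ditaxis biseriata	A3	79.79	B2	0.0154	C5	-0.1793
NEU	78	Libelloides macaronius	A2	74.5	B3	0.0719	C5	-0.1767
NEU	79	Polystoechotes punctatus	A3	78.96	B1	-0.0287	C5	-0.1612
MEG	80	Corydalus cornutus	A2	74.90	B2	0.0140	C3	-0.2620
MEG	81	Protohermes concolorus	A3	75.83	B1	-0.0111	C3	-0.2539
MEG	82	Sialis hamata	A3	78.32	B2	0.0145	C5	-0.1711
RPH	83	Mongoloraphidia harmandi	A4	80.31	B2	0.0230	C4	-0.2277
MCP	84	Neopanorpa pulchra	A3	76.38	B1	-0.0139	C5	-0.1676
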