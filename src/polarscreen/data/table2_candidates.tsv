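id	detected_median_mass	detected_mean_rt_min	n_samples	rsd_rt_pct	compound_name	inchikey	rel_mass_diff_ppm	logd_ph7
1	75.0688	13.8	10	0.3	3-Aminopropan-1-ol	WUGQZFFCHPXWKQ-UHFFFAOYSA-N	5.3	-3.9
1	75.0688	13.8	10	0.3	1-Aminopropan-2-ol	HXKKHQJGJAFBHI-UHFFFAOYSA-N	5.3	-3.4
1	75.0688	13.8	10	0.3	2-Methylaminoethanol	OPKOKAMJFNKNAS-UHFFFAOYSA-N	5.3	-3.6
1	75.0688	13.8	10	0.3	2-Amino-1-propanol	BKMMTJMQCTUHRP-UHFFFAOYSA-N	5.3	-3.5
2	102.0547	14.6	13	1.6	Guanylurea	SQSPRWMERUQXNE-UHFFFAOYSA-N	4.9	-2.1
3	103.1001	12.4	3	0.6	3-Ethoxypropylamine	SOYBEXQHNURCGE-UHFFFAOYSA-N	3.9	-3.0
3	103.1001	12.4	3	0.6	1-Dimethylaminopropan-2-ol	NCXUNZWLEYGQAH-UHFFFAOYSA-N	3.9	-2.3
3	103.1001	12.4	3	0.6	3-Dimethylaminopropan-1-ol	PYSGFFTXMUWEOT-UHFFFAOYSA-N	3.9	-2.6
4	109.0532	7.4	9	0.2	(1R,4S)-2-Azabicyclo[2.2.1]hept-5-en-3-one	DDUFYKNOXPZZIW-UHFFFAOYSA-N	3.7	-0.2
4	109.0532	7.4	9	0.2	Nicotinylalcohol	MVQVNTPHUGQQHK-UHFFFAOYSA-N	3.7	0.0
5	113.1205	11.0	3	2.8	1-Ethylpiperidine	HTLZVHNRZJPSMI-UHFFFAOYSA-N	0.9	-1.5
6	114.0795	5.6	11	0.5	1,3-Dimethylimidazolidin-2-one	CYSGHNMQYZDMIA-UHFFFAOYSA-N	1.8	-0.6
7	115.0627	12.1	11	0.8	N-(Hydroxymethyl)methacrylamide	DNTMQTKDNSEIFO-UHFFFAOYSA-N	-5.2	-0.2
7	115.0627	12.1	11	0.8	4-Morpholinecarbaldehyde	LCEDQNDDFOCWGG-UHFFFAOYSA-N	-5.2	-0.9
7	115.0627	12.1	11	0.8	N-(2-Hydroxyethyl)prop-2-enamide	UUORTJUPDJJXST-UHFFFAOYSA-N	-5.2	-0.7
7	115.0627	12.1	11	0.8	Methyl-3-aminocrotonate	XKORCTIIRYKLLG-ONEGZZNKSA-N	-5.2	-0.2
8	115.0995	7.9	15	1.7	2,6-Dimethylmorpholine	HNVIQLPOGUDBSU-UHFFFAOYSA-N	-1.7	-1.3
8	115.0995	7.9	15	1.7	Trans-4-Aminocyclohexan-1-ol	IMLXLGZJLAOKJN-UHFFFAOYSA-N	-1.7	-3.0
8	115.0995	7.9	15	1.7	2-Pyrrolidin-1-ylethanol	XBRDBODLCHKXHI-UHFFFAOYSA-N	-1.7	-2.7
9	117.0798	11.7	30	0.8	l-Valine	KZSNJWFQEVHDMF-BYPYZUCNSA-N	6.8	-2.0
9	117.0798	11.7	30	0.8	l-Norvaline	SNDPXSYFESPGGJ-BYPYZUCNSA-N	6.8	-1.9
9	117.0798	11.7	30	0.8	2-Hydroxy-N,N-dimethyl-propanamide	YEBLAXBYYVCOLT-UHFFFAOYSA-N	6.8	-0.8
10	121.0883	5.2	8	0.1	d-alpha-Methylbenzylamine	RQEUFEKYXDPUSK-SSDOTTSWSA-N	-6.6	-1.0
10	121.0883	5.2	8	0.1	Benzyl(methyl)amine	RIWRFSMVIUAEBX-UHFFFAOYSA-N	-6.6	-1.1
10	121.0883	5.2	8	0.1	l-alpha-Methylbenzylamine	RQEUFEKYXDPUSK-ZETCQYMHSA-N	-6.6	-1.0
10	121.0883	5.2	8	0.1	Phenethylamine (PEA)	BHHGXPLMPWCGHP-UHFFFAOYSA-N	-6.6	-1.2
11	126.0651	7.2	5	1.6	Melamine	JDSHMPZPIAZGSV-UHFFFAOYSA-N	-2.4	-2.0
11	126.0655	6.9	4	0.5	Melamine	JDSHMPZPIAZGSV-UHFFFAOYSA-N	0.8	-2.0
11	126.0665	8.4	9	0.2	Melamine	JDSHMPZPIAZGSV-UHFFFAOYSA-N	8.7	-2.0
12	129.0182	6.3	8	2.9	1,3,5-Triazinane-2,4,6-trione	ZFSLODLOARCGLH-UHFFFAOYSA-N	6.2	-1.1
13	135.0554	7.7	4	0.3	Adenine	GFFGJBXGBJISGV-UHFFFAOYSA-N	6.7	-0.6
14	144.0904	6.3	17	2.1	N,N′-Ethylenedi(diacetamide)	WNYIBZHOMJZDKN-UHFFFAOYSA-N	3.5	-1.8
15	149.0709	7.6	4	0.6	3-Methyladenine	ZPBYVFQJHWLTFB-UHFFFAOYSA-N	5.4	-0.3
15	149.0709	7.6	4	0.6	1-Methyladenine	SATCOUWSAZBIJO-UHFFFAOYSA-N	5.4	-0.5
15	149.0709	7.6	4	0.6	9-Methyladenine	WRXCXOUDSPTXNX-UHFFFAOYSA-N	5.4	-0.3
15	149.0709	7.6	4	0.6	7-Methyladenine	HCGHYQLFMPXSDU-UHFFFAOYSA-N	5.4	-0.4
16	149.1046	12.2	10	1.0	2,2′,2″-Nitrilotriethanol	GSEJCLTVZPLZKY-UHFFFAOYSA-N	-4.0	-3.3
16	149.1046	12.2	10	1.0	2-(Dimethylamino)-2-(hydroxymethyl)propane-1,3-diol	FGLZHYIVVZTBQJ-UHFFFAOYSA-N	-4.0	-3.4
17	149.1052	11.2	17	1.0	2,2′,2″-Nitrilotriethanol	GSEJCLTVZPLZKY-UHFFFAOYSA-N	0.0	-3.3
17	149.1052	11.2	17	1.0	2-(Dimethylamino)-2-(hydroxymethyl)propane-1,3-diol	FGLZHYIVVZTBQJ-UHFFFAOYSA-N	0.0	-3.4
18	155.1311	8.6	19	3.0	2,2,6,6-Tetramethyl-4-piperidone	JWUXJYZVKZKLTJ-UHFFFAOYSA-N	0.6	-0.3
18	155.1311	8.6	19	3.0	2-[(Dimethylamino)methyl]cyclohexanone	QDHLEFBSGUGHCL-UHFFFAOYSA-N	0.6	-0.3
19	155.1316	6.2	17	1.7	2,2,6,6-Tetramethyl-4-piperidone	JWUXJYZVKZKLTJ-UHFFFAOYSA-N	3.9	-0.3
19	155.1316	6.2	17	1.7	2-[(Dimethylamino)methyl]cyclohexanone	QDHLEFBSGUGHCL-UHFFFAOYSA-N	3.9	-0.3
20	161.1413	15.1	3	0.9	2-[2-(Diethylamino)ethoxy]ethanol	VKBVRNHODPFVHK-UHFFFAOYSA-N	-1.9	-2.2
20	161.1413	15.1	3	0.9	(2,2-Diethoxyethyl)dimethylamine	SSFAUOAQOOISRQ-UHFFFAOYSA-N	-1.9	-0.1
20	161.1413	15.1	3	0.9	7,7-Dimethyl-3-oxa-6-azaoctan-1-ol	YDEDDFNFQOPRQJ-UHFFFAOYSA-N	-1.9	-2.6
21	163.0859	15.0	6	0.5	Bicine	FSVCELGFZIQNCK-UHFFFAOYSA-N	8.6	-4.4
21	163.0859	15.0	6	0.5	3,4,5-Piperidinetriol, 2-(hydroxymethyl)-, (2R,3R,4R,5S)-	LXBIFEVIBLOUGU-JGWLITMVSA-N	8.6	-4.0
22	170.0932	7.3	3	0.4	(1R,3S)-2,2-Dimethyl-3-(2-oxopropyl)cyclopropanecarboxylic acid	BKUHNVYPRVILOX-BQBZGAKWSA-N	-6.5	-1.6
23	171.0907	7.9	8	0.3	Ethyl 2-oxopyrrolidine-1-acetate	AQZWKPDVWWJWRY-UHFFFAOYSA-N	7.0	-0.4
24	187.1211	8.1	10	0.2	(3R)-3-(2-Amino-2-oxoethyl)-5-methylhexanoic acid	NPDKTSLVWGFPQG-UHFFFAOYSA-N	1.6	-1.5
25	191.1518	6.6	11	1.8	1,1′,1″-Nitrilotripropan-2-ol	SLINHMUFWFWBMU-UHFFFAOYSA-N	-1.6	-2.9
25	191.1523	8.3	3	1.3	1,1′,1″-Nitrilotripropan-2-ol	SLINHMUFWFWBMU-UHFFFAOYSA-N	1.1	-2.9
26	201.1733	9.5	33	2.1	4-Hydroxy-2,2,6,6-tetramethylpiperidine-1-ethanol	STEYNUVPFMIUOY-UHFFFAOYSA-N	2.0	-2.6
26	201.1734	10.9	11	0.3	4-Hydroxy-2,2,6,6-tetramethylpiperidine-1-ethanol	STEYNUVPFMIUOY-UHFFFAOYSA-N	2.5	-2.6
26	201.1737	8.4	3	2.1	4-Hydroxy-2,2,6,6-tetramethylpiperidine-1-ethanol	STEYNUVPFMIUOY-UHFFFAOYSA-N	4.0	-2.6
26	201.1740	9.8	5	0.7	4-Hydroxy-2,2,6,6-tetramethylpiperidine-1-ethanol	STEYNUVPFMIUOY-UHFFFAOYSA-N	5.5	-2.6
26	201.1742	10.9	11	0.3	4-Hydroxy-2,2,6,6-tetramethylpiperidine-1-ethanol	STEYNUVPFMIUOY-UHFFFAOYSA-N	6.5	-2.6
27	205.0599	11.8	6	0.9	Methylglycinediacetic acid	CIEZZGWIJBXOTE-UHFFFAOYSA-N	6.3	-9.9
28	205.1304	7.7	7	0.5	Panthenol, dl-form	SNPLKNRPJHDVJA-UHFFFAOYSA-N	-4.9	-1.7
28	205.1304	7.7	7	0.5	Dexpanthenol	SNPLKNRPJHDVJA-ZETCQYMHSA-N	-4.9	-1.7
29	205.1327	5.7	11	0.1	Panthenol, dl-form	SNPLKNRPJHDVJA-UHFFFAOYSA-N	6.3	-1.7
29	205.1327	5.7	11	0.1	Phenformin	ICFJFFQQTFMIBG-UHFFFAOYSA-N	0.0	-3.8
29	205.1327	5.7	11	0.1	Dexpanthenol	SNPLKNRPJHDVJA-ZETCQYMHSA-N	6.3	-1.7
30	221.1402	12.2	5	0.2	3,4-Methylenedioxypropylamphetamine	LBXMQBTXOLBCCA-UHFFFAOYSA-N	-6.3	-0.3
31	222.1475	6.0	7	0.3	Bis(2-(2-Methoxyethoxy)ethyl) ether	ZUHZGEOKBKGPSW-UHFFFAOYSA-N	3.6	-0.1
31	222.1475	6.0	7	0.3	2-Ethyl-1-(2-(1,3-dioxanyl)ethyl)-pyridinium	HNGQYAWKWBGGDR-UHFFFAOYSA-N	-6.3	-2.4
32	234.1106	6.6	8	3.9	2,2′-[Ethane-1,2-diylbis(oxy)]bisethyl diacetate	OVOUKWFJRHALDD-UHFFFAOYSA-N	1.3	-0.4
33	257.1052	13.7	9	0.7	Tolmetin	UPSPUYADGBWSHF-UHFFFAOYSA-N	0.0	-0.2
34	267.1475	12.5	8	0.6	Metoprolol acid	PUQIRTNPJRFRCZ-UHFFFAOYSA-N	1.5	-1.2
35	283.1775	12.0	11	0.1	Alpha-Hydroxymetoprolol	OFRYBPCSEMMZHR-UHFFFAOYSA-N	-3.2	-1.7
36	360.2144	12.1	7	0.3	Butylscopolamin	YBCNXCRZPWQOBR-FAQYLHNASA-N	-7.0	-1.9
36	360.2144	12.1	7	0.3	Butylscopolammonium	YBCNXCRZPWQOBR-MWGADRMYSA-N	-7.0	-1.9
37	362.1668	9.9	16	0.5	Protirelin	XNSAINXGIQZQOO-SRVKXCTJSA-N	-9.7	-3.4
38	468.2676	11.6	4	0.2	6,6′,6″-(1,3,5-Triazine-2,4,6-triyltrimino)tris-hexanoic acid	BKKWPPMEXIXECW-UHFFFAOYSA-N	-4.3	-5.3
39	475.2971	6.4	22	2.2	Netilimicin	CIDUJQMULVCIBT-IULVMANBSA-N	-7.4	-12.8
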