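organism	taxon	size_mb	total_orfs	tbdt	tbdt_density	abc	abc_density	pts	trap	trophic_strategy
Citromicrobium bathyomarinum JL354	Alphaproteobacteria-Sphingomonadales	3.27	3235	27	8	22	7	1	0	N/A
Citromicrobium sp. JLT1363	Alphaproteobacteria-Sphingomonadales	3.12	3003	31	10	25	8	1	1	N/A
Erythrobacter litoralis HTCC2594	Alphaproteobacteria-Sphingomonadales	3.05	3011	18	6	23	8	3	0	extreme oligotrophs
Sphingomonas wittichii RW1	Alphaproteobacteria-Sphingomonadales	5.92	4850	134	23	34	6	4	0	extreme oligotrophs
Roseobacter denitrificans OCh 114	Alphaproteobacteria-Roseobacter clade	4.32	4129	1	0	110	25	2	22	extreme oligotrophs
Dinoroseobacter shibae DFL 12	Alphaproteobacteria-Roseobacter clade	4.42	4192	3	1	86	19	4	28	extreme oligotrophs
Ruegeria pomeroyi DSS-3	Alphaproteobacteria-Roseobacter clade	4.6	4252	0	0	102	22	4	26	moderate copiotrophs
Candidatus Pelagibacter ubique HTCC1062	Alphaproteobacteria-SAR11 clade	1.31	1354	0	0	24	18	0	3	extreme oligotrophs
Candidatus Pelagibacter ubique HTCC1002	Alphaproteobacteria-SAR11 clade	1.33	1393	0	0	23	17	0	2	extreme oligotrophs
Rhodopseudomonas palustris CGA009	Alphaproteobacteria	5.46	4820	17	3	117	21	5	8	moderate oligotrophs
Prochlorococcus marinus str. MIT 9202	Cyanobacteria	1.69	1890	1	1	40	24	0	0	extreme oligotrophs
Prochlorococcus marinus str. MIT 9301	Cyanobacteria	1.64	1906	0	0	33	20	0	0	extreme oligotrophs
Synechococcus sp. WH 7803	Cyanobacteria	2.37	2533	0	0	47	20	0	0	extreme oligotrophs
Synechococcus sp. WH 8102	Cyanobacteria	2.43	2519	0	0	50	21	0	0	extreme oligotrophs
Synechococcus sp. PCC 7002	Cyanobacteria	3.41	3187	6	2	78	23	0	0	extreme oligotrophs
Cytophaga hutchinsonii ATCC 33406	CFB group bacteria	4.43	3785	5	1	42	9	0	0	moderate copiotrophs
Flavobacteria bacterium BBFL7	CFB group bacteria	3.08	2592	10	3	32	10	0	1	moderate copiotrophs
Flavobacterium johnsoniae UW101	CFB group bacteria	6.1	5017	47	8	41	7	0	0	moderate copiotrophs
Flavobacteria bacterium MS024-3C	CFB group bacteria	1.52	1384	7	5	16	11	0	0	N/A
Polaribacter sp. MED152	CFB group bacteria	2.97	2611	10	3	22	7	0	0	N/A
Salinibacter ruber DSM 13855	CFB group bacteria	3.59	2801	16	4	59	16	0	3	moderate copiotrophs
gamma proteobacterium HTCC2207	Gammaproteobacteria-SAR92 clade	2.62	2388	17	6	21	8	2	1	extreme oligotrophs
gamma proteobacterium NOR5-3	Gammaproteobacteria-NOR5/OM60 clade	4.20	3671	27	6	37	9	2	2	extreme oligotrophs
gamma proteobacterium HTCC2143	Gammaproteobacteria-BD1-7 clade	3.93	3662	22	6	39	10	2	2	extreme oligotrophs
gamma proteobacterium HTCC2148	Gammaproteobacteria-NOR5/OM60 clade	4.31	3827	37	9	49	11	2	2	extreme oligotrophs
gamma proteobacterium HTCC2080	Gammaproteobacteria-NOR5/OM60 clade	3.58	3185	28	8	17	5	2	1	extreme oligotrophs
Congregibacter litoralis KT71	Gammaproteobacteria-NOR5/OM60 clade	4.33	3941	26	6	27	6	2	2	extreme oligotrophs
Pseudoalteromonas haloplanktis TAC125	Gammaproteobacteria-Alteromonadales	3.85	3485	34	9	29	8	4	0	moderate copiotrophs
Idiomarina loihiensis L2TR	Gammaproteobacteria-Alteromonadales	2.84	2628	28	10	29	10	4	0	moderate copiotrophs
Shewanella baltica OS185	Gammaproteobacteria-Alteromonadales	5.31	4394	33	6	53	10	7	3	extreme copiotrophs
Alteromonadales bacterium TW-7	Gammaproteobacteria-Alteromonadales	4.10	3783	32	8	42	10	4	0	N/A
gamma proteobacterium NOR51-B	Gammaproteobacteria	3.26	2930	32	10	44	13	4	3	N/A
Nitrosococcus oceani ATCC19707	Gammaproteobacteria	3.52	3017	7	2	34	10	5	1	moderate oligotrophs
Vibrio vulnificus YJ016	Gammaproteobacteria	5.21	5098	7	1	95	18	24	9	extreme copiotrophs
Photobacterium profundum SS9	Gammaproteobacteria	6.40	5489	7	1	84	13	5	10	extreme copiotrophs
Acinetobacter baumannii ATCC17978	Gammaproteobacteria-Acinetobacter	4.00	3367	22	6	34	9	2	0	moderate oligotrophs
Acinetobacter sp. ADP1	Gammaproteobacteria-Acinetobacter	3.60	3307	22	6	38	11	3	0	moderate oligotrophs
Nitrosomonas europaea ATCC 19718	Betaproteobacteria	2.81	2461	30	11	43	15	4	0	moderate oligotrophs
Ralstonia eutropha H16	Betaproteobacteria	4.05	3651	17	4	65	16	6	5	moderate oligotrophs
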