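Gene	AccessionNumber	Chromosome Location	Exon Count	Gene Length (bp)	Protein Length (aa)
RPSA	LOC100707344	LG4	8	2836	307
RPS2	LOC100693457	LG4	7	2113	279
RPS3	LOC100696630	LG14	7	6031	245
RPS3A	LOC100690034	LG6	6	3940	266
RPS4	LOC100709648	LG3	7	7165	263
RPS5	LOC100691205	LG22	6	3187	203
RPS6	LOC100707655	LG6	6	4440	249
RPS7	LOC100704343	LG15	7	6283	194
RPS8	LOC100693356	LG18	6	4026	208
RPS9	LOC100694704	LG11	5	2450	194
RPS10	LOC100708197	LG5	6	4577	166
RPS11	LOC100696602	LG4	5	2026	161
RPS12	LOC100534443	LG15	5	2914	132
RPS13	LOC100696829	LG7	6	2934	151
RPS14	LOC100696222	LG10	5	2925	151
RPS15	LOC100695708	LG18	4	2627	145
RPS15A	LOC100698782	LG6	5	5166	130
RPS16	LOC100703910	LG17	6	3101	146
RPS17a	LOC100691912	LG7	5	7981	134
RPS17b	LOC100699764	LG1	5	5281	134
RPS18	LOC100699803	LG22	6	3445	152
RPS19a	LOC100689943	LG11	6	6770	146
RPS19b	LOC100690398	LG22	5	7095	152
RPS20	LOC100696588	LG9	4	1505	119
RPS21	LOC100701551	LG20	6	4172	83
RPS23	LOC100690746	LG5	4	2080	143
RPS24	LOC100700493	LG13	5	4576	131
RPS25	LOC100690179	LG14	5	2542	123
RPS26	LOC100700449	LG5	4	1749	115
RPS27-1a	LOC100705775	LG11	4	5189	84
RPS27-1b	LOC100696027	LG22	4	2376	84
RPS27-2a	LOC100691333	LG7	4	2298	84
RPS27-2b	LOC100690174	LG23	4	2477	84
RPS27A	LOC100697017	LG13	6	2770	156
RPS28	LOC100696499	LG18	4	2909	69
RPS29	LOC100703241	LG15	3	1056	56
RPS30	LOC100704053	LG15	5	1783	133
RPL3-1	LOC100711099	LG4	9	4294	403
RPL3-2	LOC100694819	LG4	10	3972	408
RPL4	LOC100694481	LG7	10	3520	369
RPL5a	LOC100708520	LG23	8	6819	297
RPL5b	LOC100700425	LG18	8	3792	298
RPL6	LOC100699139	LG12	6	6639	227
RPL7-1	LOC100702526	LG9	7	4215	245
RPL7-2	LOC100700318	LG15	7	4406	246
RPL7A	LOC100693537	LG7	8	3256	266
RPL8	LOC100706674	LG16	6	3269	257
RPL9	LOC100703191	LG6	8	5781	192
RPL10	LOC100697190	LG20	6	3989	215
RPL10A	LOC100702190	LG20	6	1982	216
RPL11	LOC100695881	LG22	6	3847	178
RPL12	LOC100695084	LG1	6	3525	165
RPL13	LOC100712089	LG1	6	4141	211
RPL13A	LOC100708460	LG19	7	3290	205
RPL14	LOC100534449	LG22	6	3561	137
RPL15	LOC100697988	LG22	4	2672	204
RPL17	LOC100707041	LG7	7	4249	184
RPL18	LOC100534549	LG11	7	5614	188
RPL18A	LOC100706131	LG17	5	3492	176
RPL19a	LOC100706003	LG8	6	2335	195
RPL19b	LOC100709589	LG4	6	3080	194
RPL21	LOC100711190	LG9	6	2393	160
RPL22-1a	LOC100699599	LG20	4	3986	129
RPL22-1b	LOC100710673	LG5	4	3264	129
RPL22-2	LOC100699889	LG9	4	2079	129
RPL23	LOC100701640	LG4	5	4091	140
RPL23A	LOC100705596	LG10	5	2677	155
RPL24	LOC100707648	LG16	6	3744	157
RPL26	LOC100708525	LG2	4	3651	145
RPL27	LOC100711912	LG4	5	3838	136
RPL27A	LOC100702758	LG7	5	6769	148
RPL28	LOC100704095	LG7	5	2011	137
RPL29	LOC106098935	LG5	4	3933	64
RPL30	LOC100710306	LG22	5	3112	116
RPL31	LOC100696251	LG23	5	3056	124
RPL32	LOC100534436	LG20	4	3255	135
RPL34	LOC109195715	LG3	5	2953	117
RPL35	LOC100711334	LG12	4	2608	123
RPL35A	LOC100711077	LG14	5	4038	110
RPL36	LOC 100691103	LG17	4	3201	105
RPL36A	LOC100690460	LG2	5	4870	106
RPL37	LOC100705081	LG7	4	4669	97
RPL37A	LOC100692490	LG18	4	2432	92
RPL38	LOC100711498	LG8	5	3295	70
RPL39	LOC100692256	LG2	3	3583	51
RPL40	LOC100699676	LG12	5	3438	128
RPL41a	LOC100711481	LG20	4	911	25
RPL41b	LOC100699101	LG5	4	1905	25
RPLP0	LOC100534569	LG5	8	2532	315
RPLP1	LOC100692069	LG22	4	2095	114
RPLP2a	LOC100691806	LG1	5	2962	114
RPLP2b	LOC100697185	LG5	5	1987	114
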