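category	1141	1143	2919	2927	2931	2938	2939	2942	trna_genes
Ala	544	352	408	518	351	362	479	419	83
Arg	2	0	1	0	0	1	0	0	204
Asn	0	0	0	0	0	0	1	0	40
Asp	12	5	18	4	9	8	6	2	54
Cys	27	21	30	94	9	43	27	25	510
Gln	152	432	313	359	394	307	455	307	60
Glu	93648	88823	108094	78000	106609	78579	66925	71478	621
Gly	41814	56821	61251	60975	45043	60536	46838	49574	1795
His	75542	133863	116715	73717	140707	96272	111728	96764	25
Ile	0	0	0	0	0	0	0	0	25
Leu	3	1	4	5	1	1	2	0	49
Lys	5635	8000	6634	5972	5206	6484	6237	4596	121
Met	5	8	11	14	7	6	8	4	33
Phe	1	0	0	0	0	0	0	0	35
Pro	512	505	554	646	781	666	1277	1225	26
Ser	0	0	1	1	0	0	0	0	79
Stop	94	25	94	28	35	71	51	38	25
Thr	24	13	14	8	11	15	18	8	132
Trp	0	0	0	0	0	0	0	0	182
Tyr	0	0	0	0	0	0	0	0	48
Val	34225	37307	44317	40587	31800	40946	54467	36366	90
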