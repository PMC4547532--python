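category	28	29	30	31	32	33	34	35	36	37	38	39	40
Ala	32	584	2304	387	172	1	0	0	0	0	0	0	0
Arg	0	0	0	1	0	3	0	0	0	0	0	0	0
Asn	0	0	1	0	0	0	0	0	0	0	0	0	0
Asp	0	0	0	0	0	5	46	8	3	0	0	0	0
Cys	4	3	5	45	169	54	3	2	0	0	0	0	0
Gln	27	29	1381	1044	10	79	105	11	7	0	0	0	5
Glu	761	5235	45495	356687	112717	134146	22158	5165	916	41	58	1291	1047
Gly	2811	7191	311707	64428	34303	969	203	144	545	3	6	1	71
His	38	454	72659	119840	76384	8686	553427	27	10	0	0	0	2
Ile	0	0	0	0	0	0	0	0	0	0	0	0	0
Leu	0	0	0	0	1	3	13	0	0	0	0	0	0
Lys	454	37	1158	16529	26139	3400	895	50	29	2	1	6	69
Met	0	0	8	56	0	0	0	0	0	0	0	0	0
Phe	0	0	0	0	0	0	1	0	0	0	0	0	0
Pro	286	301	1250	2295	1001	1047	4	2	0	0	0	0	0
Ser	0	0	0	0	2	0	0	0	0	0	0	0	0
Stop	0	1	0	0	0	0	7	391	26	13	0	0	0
Thr	0	1	19	49	44	0	0	0	0	0	0	0	0
Trp	0	0	0	0	0	0	0	0	0	0	0	0	0
Tyr	0	0	0	0	0	0	0	0	0	0	0	0	0
Val	59	888	1321	80220	160655	54321	24171	30	53	40	3	8	5
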