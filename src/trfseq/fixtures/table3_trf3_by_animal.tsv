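category	1141	1143	2919	2927	2931	2938	2939	2942
Ala	1	0	1	2	1	0	0	0
Arg	1	4	4	10	1	7	2	4
Asn	13	6	18	8	3	6	14	6
Asp	6	3	9	6	3	3	6	4
Cys	0	1	0	3	0	0	0	0
Gln	2	1	1	2	1	1	0	1
Glu	34	16	41	43	25	26	24	46
Gly	0	0	1	4	0	1	2	0
His	0	0	0	0	0	0	0	0
Ile	0	1	0	0	0	0	0	0
Leu	1	0	0	0	1	0	2	2
Lys	4	2	7	2	0	5	4	12
Met	3	2	1	1	1	1	0	0
Phe	0	1	0	0	0	0	1	0
Pro	0	1	1	3	0	0	0	0
Ser	0	0	0	0	0	0	0	0
Stop	0	0	0	0	0	0	0	0
Thr	1	0	3	7	1	3	2	1
Trp	2	0	1	0	1	0	1	0
Tyr	0	1	2	0	0	1	1	0
Val	6	2	5	16	3	7	2	6
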