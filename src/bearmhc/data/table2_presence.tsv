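marker	allele	north	south
U	Urar-U*01	100	100
U	Urar-U*02	98	91
U	Urar-U*03	61	52
U	Urar-U*04	62	52
U	Urar-U*05	37	57
U	Urar-U*06	66	35
U	Urar-U*07	22	62
U	Urar-U*08	35	42
U	Urar-U*09	4	53
U	Urar-U*10	3	44
U	Urar-U*11	0	40
U	Urar-U*12	2	36
U	Urar-U*13	0	28
U	Urar-U*14	37	0
U	Urar-U*15	38	0
U	Urar-U*16	35	0
U	Urar-U*17	0	10
U	Urar-U*18	27	0
U	Urar-U*19	28	0
U	Urar-U*20	23	0
U	Urar-U*21	28	0
U	Urar-U*22	23	0
U	Urar-U*23	21	0
U	Urar-U*24	0	12
U	Urar-U*25	22	0
U	Urar-U*26	0	15
U	Urar-U*27	0	14
U	Urar-U*28	0	7
U	Urar-U*29	4	3
U	Urar-U*30	4	3
U	Urar-U*31	4	3
U	Urar-U*32	7	0
U	Urar-U*33	6	0
U	Urar-U*34	3	0
U	Urar-U*35	0	1
U	Urar-U*36	1	0
U	Urar-U*37	1	0
DRB	Urar-DRB*20	40	86
DRB	Urar-DRB*21	36	54
DRB	Urar-DRB*13	0	54
DRB	Urar-DRB*11	52	10
DRB	Urar-DRB*22	29	21
DRB	Urar-DRB*23	29	21
DRB	Urar-DRB*24	59	0
DRB	Urar-DRB*25	59	0
DRB	Urar-DRB*26	37	0
DRB	Urar-DRB*17	3	19
DRB	Urar-DRB*27	0	21
DRB	Urar-DRB*28	0	21
DRB	Urar-DRB*29	0	19
DRB	Urar-DRB*30	15	7
DRB	Urar-DRB*16	4	4
DRB	Urar-DRB*31	4	0
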