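1	121535434	124535434
2	92326171	95326171
3	90504854	93504854
4	49660117	52660117
5	46405641	49405641
6	58830166	61830166
7	58054331	61054331
8	43838887	46838887
9	47367679	50367679
10	39254935	42254935
11	51644205	54644205
12	34856694	37856694
13	16000000	19000000
14	16000000	19000000
15	17000000	20000000
16	35335801	38335801
17	22263006	25263006
18	15460898	18460898
19	24681782	27681782
20	26369569	29369569
21	11288129	14288129
22	13000000	16000000
X	58632012	61632012
Y	10104553	13104553
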