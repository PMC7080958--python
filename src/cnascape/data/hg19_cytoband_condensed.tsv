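chr1	0	121535434	p00	gneg
chr1	121535434	123035434	p11	acen
chr1	123035434	124535434	q11	acen
chr1	124535434	249250621	q00	gneg
chr2	0	92326171	p00	gneg
chr2	92326171	93826171	p11	acen
chr2	93826171	95326171	q11	acen
chr2	95326171	243199373	q00	gneg
chr3	0	90504854	p00	gneg
chr3	90504854	92004854	p11	acen
chr3	92004854	93504854	q11	acen
chr3	93504854	198022430	q00	gneg
chr4	0	49660117	p00	gneg
chr4	49660117	51160117	p11	acen
chr4	51160117	52660117	q11	acen
chr4	52660117	191154276	q00	gneg
chr5	0	46405641	p00	gneg
chr5	46405641	47905641	p11	acen
chr5	47905641	49405641	q11	acen
chr5	49405641	180915260	q00	gneg
chr6	0	58830166	p00	gneg
chr6	58830166	60330166	p11	acen
chr6	60330166	61830166	q11	acen
chr6	61830166	171115067	q00	gneg
chr7	0	58054331	p00	gneg
chr7	58054331	59554331	p11	acen
chr7	59554331	61054331	q11	acen
chr7	61054331	159138663	q00	gneg
chr8	0	43838887	p00	gneg
chr8	43838887	45338887	p11	acen
chr8	45338887	46838887	q11	acen
chr8	46838887	146364022	q00	gneg
chr9	0	47367679	p00	gneg
chr9	47367679	48867679	p11	acen
chr9	48867679	50367679	q11	acen
chr9	50367679	141213431	q00	gneg
chr10	0	39254935	p00	gneg
chr10	39254935	40754935	p11	acen
chr10	40754935	42254935	q11	acen
chr10	42254935	135534747	q00	gneg
chr11	0	51644205	p00	gneg
chr11	51644205	53144205	p11	acen
chr11	53144205	54644205	q11	acen
chr11	54644205	135006516	q00	gneg
chr12	0	34856694	p00	gneg
chr12	34856694	36356694	p11	acen
chr12	36356694	37856694	q11	acen
chr12	37856694	133851895	q00	gneg
chr13	0	16000000	p00	gneg
chr13	16000000	17500000	p11	acen
chr13	17500000	19000000	q11	acen
chr13	19000000	115169878	q00	gneg
chr14	0	16000000	p00	gneg
chr14	16000000	17500000	p11	acen
chr14	17500000	19000000	q11	acen
chr14	19000000	107349540	q00	gneg
chr15	0	17000000	p00	gneg
chr15	17000000	18500000	p11	acen
chr15	18500000	20000000	q11	acen
chr15	20000000	102531392	q00	gneg
chr16	0	35335801	p00	gneg
chr16	35335801	36835801	p11	acen
chr16	36835801	38335801	q11	acen
chr16	38335801	90354753	q00	gneg
chr17	0	22263006	p00	gneg
chr17	22263006	23763006	p11	acen
chr17	23763006	25263006	q11	acen
chr17	25263006	81195210	q00	gneg
chr18	0	15460898	p00	gneg
chr18	15460898	16960898	p11	acen
chr18	16960898	18460898	q11	acen
chr18	18460898	78077248	q00	gneg
chr19	0	24681782	p00	gneg
chr19	24681782	26181782	p11	acen
chr19	26181782	27681782	q11	acen
chr19	27681782	59128983	q00	gneg
chr20	0	26369569	p00	gneg
chr20	26369569	27869569	p11	acen
chr20	27869569	29369569	q11	acen
chr20	29369569	63025520	q00	gneg
chr21	0	11288129	p00	gneg
chr21	11288129	12788129	p11	acen
chr21	12788129	14288129	q11	acen
chr21	14288129	48129895	q00	gneg
chr22	0	13000000	p00	gneg
chr22	13000000	14500000	p11	acen
chr22	14500000	16000000	q11	acen
chr22	16000000	51304566	q00	gneg
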