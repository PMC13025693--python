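# id=ON060364	organism=Amphitretus_pelagicus	length=17380	circular=true
gene	from	to	size	strand	start_codon	stop_codon
COIII	10	807	798	L	ATA	TAA
trnK	813	881	69	L
trnA	882	945	64	L
trnR	947	1008	62	L
trnN	1009	1076	68	L
trnI	1077	1142	66	L
ND3	1143	1439	351	L	ATG	TAA
trnS1	1492	1560	69	L
ND2	1561	2601	1041	L	ATG	TAA
COI	2573	4105	1533	L	ATG	TAA
COII	4107	4793	687	L	ATG	TAA
trnD	4792	4855	64	L
ATP8	4856	5011	156	L	ATG	TAA
ATP6	5016	5705	690	L	ATA	TAG
trnF	5731	5795	65	H
ND5	5796	7482	1687	H	ATG	T--
trnH	7483	7546	64	H
ND1	7564	8508	945	H	ATA	TAG
trnL2	8506	8570	65	H
trnC	8597	8661	65	H
trnY	8662	8724	63	H
trnE	8734	8797	64	H
ND4	9907	11241	1335	H	ATT	TAG
ND4L	11247	11543	297	H	ATG	TAG
trnT	11548	11612	65	L
trnS2	11613	11676	64	H
Cytb	11675	12814	1140	H	ATG	TAA
ND6	12807	13319	513	H	ATG	TAG
trnP	13321	13385	65	H
trnL1	13598	13665	68	H
16S	13631	15028	1398	H
trnV	15000	15067	68	H
12S	15080	16025	946	H
trnM	16029	16094	66	H
trnW	16131	16196	66	H
trnQ	16197	16264	68	H
trnG	16267	16336	70	H
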