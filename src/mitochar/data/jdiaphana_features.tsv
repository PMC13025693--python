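# id=ON060363	organism=Japetella_diaphana	length=16111	circular=true
gene	from	to	size	strand	start_codon	stop_codon
COIII	17	808	792	L	ATT	TAA
trnK	820	888	69	L
trnA	889	956	68	L
trnR	965	1027	63	L
trnN	1029	1098	70	L
trnI	1100	1165	66	L
ND3	1166	1516	351	L	ATG	TAA
trnS1	1515	1583	69	L
ND2	1584	2621	1038	L	ATG	TAA
COI	2593	4125	1533	L	ATG	TAA
COII	4129	4818	690	L	ATG	TAA
trnD	4817	4882	66	L
ATP8	4884	5036	153	L	ATG	TAA
ATP6	5039	5731	693	L	ATG	TAG
trnF	5755	5820	66	H
ND5	5821	7513	1693	H	ATG	T--
trnH	7514	7579	66	H
ND4	7580	8896	1317	H	ATA	TAA
ND4L	8920	9216	297	H	ATG	TAG
trnT	9221	9285	65	L
trnS2	9295	9359	65	H
Cytb	9358	10497	1140	H	ATG	TAA
ND6	10490	11002	513	H	ATG	TAG
trnP	11004	11068	65	H
ND1	11073	12014	942	H	ATG	TAA
trnL2	12015	12079	65	H
trnL1	12080	12143	64	H
16S	12104	13500	1397	H
trnV	13470	13536	67	H
12S	13546	14460	915	H
trnM	14459	14527	69	H
trnC	14536	14599	64	H
trnY	14600	14663	64	H
trnW	14664	14734	71	H
trnQ	14735	14802	68	H
trnG	14803	14866	64	H
trnE	14867	14934	68	H
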