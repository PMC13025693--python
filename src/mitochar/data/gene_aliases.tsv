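# Editable gene-name normalization map: alias -> canonical symbol.
# Lookup is case-insensitive on the alias column.
alias	canonical
COX1	COI
COX2	COII
COX3	COIII
CO1	COI
CO2	COII
CO3	COIII
COB	Cytb
CYTB	Cytb
CYB	Cytb
NAD1	ND1
NAD2	ND2
NAD3	ND3
NAD4	ND4
NAD4L	ND4L
NAD5	ND5
NAD6	ND6
ATPASE6	ATP6
ATPASE8	ATP8
RRNL	16S
RRNS	12S
L-RRNA	16S
S-RRNA	12S
16S-RRNA	16S
12S-RRNA	12S
TRNA-SER(UCN)	trnS2
TRNA-SER(AGN)	trnS1
TRNA-LEU(UUR)	trnL2
TRNA-LEU(CUN)	trnL1
TRNA-ALA	trnA
TRNA-ARG	trnR
TRNA-ASN	trnN
TRNA-ASP	trnD
TRNA-CYS	trnC
TRNA-GLN	trnQ
TRNA-GLU	trnE
TRNA-GLY	trnG
TRNA-HIS	trnH
TRNA-ILE	trnI
TRNA-LYS	trnK
TRNA-MET	trnM
TRNA-PHE	trnF
TRNA-PRO	trnP
TRNA-THR	trnT
TRNA-TRP	trnW
TRNA-TYR	trnY
TRNA-VAL	trnV
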