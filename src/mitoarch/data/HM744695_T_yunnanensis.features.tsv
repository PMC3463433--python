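gene	class	strand	start	end	start_codon	stop_codon	anticodon
trnI	tRNA	J	1	67			GAT
trnQ	tRNA	N	95	163			TTG
trnM	tRNA	J	169	238			CAT
nad2	PCG	J	239	1258	ATT	TAA
trnW	tRNA	J	1260	1326			TCA
trnC	tRNA	N	1319	1385			GCA
trnY	tRNA	N	1391	1457			GTA
cox1	PCG	J	1460	2990	CGA	T--
trnL(UUR)	tRNA	J	2991	3059			TAA
cox2	PCG	J	3062	3743	ATG	T--
trnK	tRNA	J	3744	3814			CTT
trnD	tRNA	J	3814	3879			GTC
atp8	PCG	J	3880	4041	ATA	TAA
atp6	PCG	J	4035	4711	ATG	TA-
cox3	PCG	J	4712	5500	ATG	TAA
trnG	tRNA	J	5503	5568			TCC
nad3	PCG	J	5569	5920	ATA	T--
trnA	tRNA	J	5921	5989			TGC
trnR	tRNA	J	5993	6058			TCG
trnN	tRNA	J	6067	6132			GTT
trnS(AGN)	tRNA	J	6133	6193			TCT
trnE	tRNA	J	6194	6259			TTC
trnF	tRNA	N	6262	6330			GAA
nad5	PCG	N	6331	8068	ATT	T--
trnH	tRNA	N	8069	8135			GTG
nad4	PCG	N	8137	9477	ATG	TAA
nad4L	PCG	N	9478	9770	ATG	TA-
trnT	tRNA	J	9773	9838			TGT
trnP	tRNA	N	9839	9903			TGG
nad6	PCG	J	9906	10429	ATA	TA-
cob	PCG	J	10430	11575	ATG	TAA
trnS(UCN)	tRNA	J	11580	11650			TGA
nad1	PCG	N	11666	12598	TTG	TAA
trnL(CUN)	tRNA	N	12599	12667			TAG
rrnL	rRNA	N	12668	13996
trnV	tRNA	N	13997	14061			TAC
rrnS	rRNA	N	14062	14838
at_rich_region	control	J	14839	15816
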