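gene	class	strand	start	end	start_codon	stop_codon	anticodon
trnI	tRNA	J	1	65			GAT
trnQ	tRNA	N	66	134			TTG
trnM	tRNA	J	139	208			CAT
nad2	PCG	J	209	1226	ATT	T--
trnW	tRNA	J	1227	1292			TCA
trnC	tRNA	N	1285	1351			GCA
trnY	tRNA	N	1358	1424			GTA
cox1	PCG	J	1427	2957	CGA	T--
trnL(UUR)	tRNA	J	2958	3026			TAA
cox2	PCG	J	3028	3709	ATG	T--
trnK	tRNA	J	3710	3780			CTT
trnD	tRNA	J	3780	3844			GTC
atp8	PCG	J	3845	4006	ATA	TAA
atp6	PCG	J	4000	4676	ATG	TA-
cox3	PCG	J	4677	5465	ATG	TAA
trnG	tRNA	J	5468	5533			TCC
nad3	PCG	J	5534	5885	ATT	T--
trnA	tRNA	J	5886	5954			TGC
trnR	tRNA	J	5958	6023			TCG
trnN	tRNA	J	6028	6093			GTT
trnS(AGN)	tRNA	J	6094	6153			TCT
trnE	tRNA	J	6154	6218			TTC
trnF	tRNA	N	6221	6286			GAA
nad5	PCG	N	6287	8024	ATT	T--
trnH	tRNA	N	8025	8091			GTG
nad4	PCG	N	8093	9433	ATG	TAA
nad4L	PCG	N	9434	9726	ATG	TA-
trnT	tRNA	J	9729	9794			TGT
trnP	tRNA	N	9795	9858			TGG
nad6	PCG	J	9861	10384	ATA	TA-
cob	PCG	J	10385	11530	ATG	TAA
trnS(UCN)	tRNA	J	11536	11608			TGA
nad1	PCG	N	11624	12556	TTG	TAA
trnL(CUN)	tRNA	N	12557	12627			TAG
rrnL	rRNA	N	12628	13962
trnV	tRNA	N	13963	14027			TAC
rrnS	rRNA	N	14028	14806
at_rich_region	control	J	14807	16173
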