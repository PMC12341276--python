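name	rrna	start	end	sequence
Hu_1	5.8S	86	118	/5Biosg/GGGGCCGCAAGTGCGTTCGAAGTGTCGATGATC
Hu_2	5.8S	132	156	/5Biosg/AAGCGACGCTCAGACAGGCGTAGCC
Hu_3	18S	205	233	/5Biosg/GTTTTGATCTGATAAATGCACGCATCCCC
Hu_4	18S	285	314	/5Biosg/ATCGGCCCGAGGTTATCTAGAGTCACCAAA
Hu_5	18S	840	867	/5Biosg/CATTATTCCTAGCTGCGGTATCCAGGCG
Hu_6	28S	1	34	/5Biosg/TTCAGCGGGTCGCCACGTCTGATCTGAGGTCGCG
Hu_7	28S	194	219	/5Biosg/CTGGGCCTCGATCAGAAGGACTTGGG
Hu_8	28S	935	960	/5Biosg/TCCCTCGGCCCCGGGATTCGGCGAGT
Hu_9	28S	1067	1094	/5Biosg/CGCGCCGTGGGAGGGGTGGCCCGGCCCC
Hu_10	28S	1442	1468	/5Biosg/GGCCGGTGGTGCGCCCTCGGCGGACTG
Hu_11	28S	4060	4100	/5Biosg/GCTCGCCCCCCCGCCTCACCGGGTCAGTGAAAAAACGATCA
Hu_12	28S	4742	4782	/5Biosg/GACAGGCGGGGGACCGGCTATCCGAGGCCAACCGAGGCTCC
Hu_13	28S	4964	4990	/5Biosg/GAAGCAGGTCGTCTACGAATGGTTTAG
Hu_14	28S	5035	5064	/5Biosg/CCCTTGTGTCGAGGGCTGACTTTCAATAGA
Hu_15	18S	1719	1743	/5Biosg/CGAGGGCCTCACTAAACCATCCAAT
Hu_16	18S	1788	1813	/5Biosg/TAGATAGTCAAGTTCGACCGTCTTCT
Hu_17	28S	141	165	/5Biosg/TCTTCCGTACGCCACATGTCCCGCG
Hu_18	28S	709	734	/5Biosg/CTTCCCAGCCGTCCCGGAGCCGGTCG
Hu_19	28S	1722	1751	/5Biosg/TCTAATCATTCGCTTTACCGGATAAAACTG
Hu_20	28S	4036	4060	/5Biosg/AGAGTAGTGGTATTTCACCGGCGGC
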