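group	donor_interval	donor_flank	insertion	acceptor_flank	acceptor_interval	homology
WT	4648:4677	GGGACCCAGGCTttGAAGGCAATCCTGGGA	GCACTTC	GTACTTATAGAGGAACAGGGGCAGcgTAGA	2888:2917
WT	5161:5190	ACTGTAATGAACTGGAATGAGCTGGGCCGC	CCT	GGAAATCAGGACAGGTACAAGcGTGTGGAT	7925:7954
WT	5291:5320	TTCTGAGCTGAGATGAGCTGGaGTGAGCTC	TTACC	GGTAGCTATAGGGAATACAGAACAGGTGGG	2653:2682
WT	4974:5003	GAAGGCgAGACTCATAAAGCTTGCTGAGCA	CCAGGACA	CCCTGTAGGGTAGCTGTAGGGAAATCAGGA	7906:7935	Sgamma2278:2285
WT	5206:5235	TGGCTTAACCGAGATGAGCCAAACTGGAAT	CCC	GAATAGCTACAGGGGAGCCAGGAGAGGTAG	2753:2782
WT	4891:4920	AATTGAGAAAGAATAGAGACCTGCAGTTGA	TC	CTGATGGCAAATGGAAGGGCAGAGACCCAG	2957:2986
WT	5110:5139	AGGTGATTACTCTGAGGTAAGCAAAGCTGG	CA	CCAGGTCTGCAGCTACATACGGGTAAGCAG	2694:2723
WT	5297:5326	GCTGAGATGAGCTGGGGTGAGCTCAGCTAT	TT	TATAGGGAGCCAGGACAGGTGGAAGTGTGG	7602:7631
WT	4667:4696	CAATCggGGGATTCTGGAAGAAAAGATGTT	CC	GGATCAAGGCAGAACAGGTCCAGGGGTGCC	2840:2869
WT+NU7026	5432:5461	TAGGGTGAGCTGAGCTGGGTGAGCTGAGCT	CCCAGT	AGTGTGGGGATCCAGGTAAGGCTGGACTGG	8264:8293
WT+NU7026	4620:4649	TGGAAGCTAATTTAGAATCAAGTAAGGAGG	CAAGACAGGTGG--GTGTGGGGATCAAGG	AGGAGAAATGGAAGAATGCAGATTCCAAAC	8030:8059	Sgamma2820:2848
WT+NU7026	4907:4936	AGACCTGCAGTTGAGGCCAGCAGGTCGGCT	ACTA	TGGAACTGTGGGGACCCTGTAGGGTAGCTG	7892:7921
WT+NU7026	4787:4816	GTTGTTAAAGAATGGTATCAAAGGACAGTG	CTAgAAcGTAcT	TCAAGGCAGAACAGGTCCAGGGGTGCCAGG	2843:2872	Smu3545:3556
WT+NU7026	5231:5260	GGAATGAACTTCATTAATCTAGGTTGAATA	GGTGGAAGTGTGGGG	AGGGCAGCCAGGACAGGTGGAAATGTGGTG	7750:7779	Sgamma4882:4896
WT+NU7026	4879:4908	ACAGCTGTACAGAATTGAGAAAGAATAGAG	TGGGG--AGCTCAGCTATGCTAC-CGTGTTG-GG	CAGGAAGAATAGCTACAGGGGAGCCAGGAG	2747:2776	Smu5309:5342
WT+NU7026	5291:5320	TTCTGAGCTGAGATGAGCTGGaGTGAGCTC	TTACC	GGTAGCTATAGGGAATACAGAACAGGTGGG	2653:2682
WT+NU7026	4974:5003	GAAGGCgAGACTCATAAAGCTTGCTGAGCA	CTACGACA	CCCTGTAGGGTAGCTGTAGGGAAATCAGGA	7906:7935
WT+NU7026	5237:5266	AACTTCATTAATCTAGGTTGAATAGAGCTA	GAC--GTaGCATTGTGTGacTC	CAGGCACAGTAGCTATAGGGGaGCCAAGAC	2796:2825	Sgamma2575:2596
WT+NU7026	4989:5018	AAAGCTTGCTGAGCAAAATTAAGGGAACAA	TTGAG	TGAGGCAGGTAAGAGTGTGGGAACCCAGTC	8429:8458
WT+NU7026	5245:5274	TAATCTAGGTTGAATAGAGCTAAACTCTAC	AGTGCAGA	TGAGGCAGGTAAGAGTGTGGGAACCCAGTC	8429:8458	Sgamma8821:8828
WT+NU7026	4685:4714	AGAAAAGATGTTTTTAGTTTTTATAGAAAA	GTAAT	TATAGGGGaGCCAAGAaAGGTGGAAGTGTG	2809:2838
WT+NU7026	4796:4825	GAATGGTATCAAAGGACAGTGCTTAGATCC	GAGGTGAGTGTGAGAGGACAAA	AAGTTtAGTAgTTATAGAGGAACAGGGGCA	2881:2910	Smu4827:4845
WT+NU7026	5088:5117	GCTTCTAAcATGCGCTAAACTGAGGTGATT	CCAAGGACCCAGGCAGAGCAGCTCCAGTAGGCCA	CAAtcACAAGGGAACTGATGGCAAATGGAA	2943:2972	Sgamma4014:4035
WT+NU7026	4663:4692	AAGGCAATCtTGGGATTCTGGAAGAAAAGA	CCAT	GAAGTGTAGTGACCCttGAAGAATAGCTAC	2733:2762
WT+NU7026	5002:5031	CAAAATTAAGGGAACAAGGTTGAGAGCCCT	TC	GGAATTGTGGTGACCCAGACAAAACAGCTA	7817:7846
WT+NU7026	4684:4713	AAGAAAAGATGTTTTTAGTTTTTATAGAAA	CC	ACAGGGAAGCTATAttAAAACCAGGACAcG	8132:8161
WT+NU7026	5133:5162	AAGCTGGGCTTGAGCCAAAATGAAGTAGAC	GC	TGGAAGGGCAGAGACCCAGACTAAATGGCT	2968:2997
WT+NU7026	5210:5239	TTAACCGAGATGAGCCAAACTGGAATGAAC	TA	AAAACCAGGACAGGAGGAAGAATGGGGATC	8148:8177
WT+NU7026	4816:4845	GCTTAGATCCgAGGTGAGTGTGAGAGGACA	AA	AAGTTtAGTAgTTATAGAGGAACAGGGGCA	2881:2910
WT+NU7026	4897:4926	GAAAGAATAGAGACCTGCAGTTGAGGCCAG	TT	AGGGTGTGGATCCAGGCAGGGTAGCTATAG	2634:2663
KO	5360:5389	AGCTACTCTGGAGTAGCTGAGATGGGGTGA	TT	CAAATGGAAGGGCAGAGACCCAGACTAAAT	2964:2993
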