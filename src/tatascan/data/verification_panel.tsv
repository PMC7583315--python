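gene	rsid	allele_class	allele_label	snp_offset	sequence	predicted_neglog_kd	measured_kd_nM	measured_kd_sem_nM	rsid_conflict
SHOX	rs1452787381	WT	-45A	-45	gaggtcgccgcgtataaatagtgaga	20.31	39	7	
SHOX	rs1452787381	min	-45G	-45	gaggtcgccgcgtgtaaatagtgaga	19.21	260	70	
GTPBP6	rs1393008234	WT	-24G	-24	atcacgagcacgtgatgaggagcggc	17.30	1500	200	
GTPBP6	rs1393008234	min	-24T	-24	atcacgagcacgttatgaggagcggc	18.68	1400	200	
ASMT	rs1402972626	WT	-30G	-30	ggtgaccttttgtgcccagaataggt	18.18	600	300	
ASMT	rs1402972626	min	-30A	-30	ggtgaccttttgtacccagaataggt	18.93	1000	300	
ZFY	rs1452787381	WT	-56C	-56	ggcggagggggcccaactaccatccc	17.67	1000	400	printed rsID duplicates SHOX's; accompanying text names rs1388535808/rs996955491 for this gene
ZFY	rs1452787381	min	-56T	-56	ggcggagggggcctaactaccatccc	18.18	2000	1000	printed rsID duplicates SHOX's; accompanying text names rs1388535808/rs996955491 for this gene
CDY2A	rs20067072	WT	-24G	-24	agaatgttccatataatcgtcatagc	19.27	160	30	also printed as rs200670724; ODN written on the strand opposite to the allele labels
CDY2A	rs20067072	min	-24t	-24	agaatgttccatacaatcgtcatagc	18.76	500	200	also printed as rs200670724; ODN written on the strand opposite to the allele labels
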