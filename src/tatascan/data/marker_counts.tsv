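class_label	n_gene	n_snp	n_res	n_gt	n_lt	n_up	n_dn	printed_p_norm	printed_p_equal	note
whole_genome_norm	10000	100000	1000	200	800			>0.52		reference row: genome-wide norm for SNPs within TF-sites
clinical_tbp_markers	33	203	51	14	37			>0.93		reference row: clinically proven markers in TBP-sites
female_reproductive	22	129	24	19	5			<0.000001		reference row: female reproductive potential markers
PAR1	15	899	211	143	68	101	110	<0.000001	>0.2	table digits 143/68; accompanying text says 146 and 68
PAR2	3	135	25	20	5	10	15	<0.000001	>0.1	
paralogous	8	56	13	8	5	4	9	<0.01	>0.1	
unique	6	41	12	6	6	4	8	<0.025	>0.1	
y_linked_subtotal	32	1131	261	176	85	119	142	<0.000001	>0.06	per-class n_gt sum to 177 and n_lt to 84; printed subtotal digits kept
other_y_linked	31	75	0	0	0			 	 	no candidate markers predicted
TOTAL	63	1206	261	176	85	119	142	<0.000001	>0.06	
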