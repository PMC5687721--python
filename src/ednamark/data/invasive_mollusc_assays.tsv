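name	target_taxon	locus	primer_label	sequence_5to3	annealing_C	mg_mM	amplicon_bp	detection_limit_ng_ml
CoFl-16S	Corbicula sp.	16S	CoFl-16S-F	GAATAACTTAAATGTAGGT	55	2	165	0.375
CoFl-16S	Corbicula sp.	16S	CoFl-16S-R	AGCAAACTTCTTCTTAAATAT	55	2	165	0.375
MeTu-16S	Melanoides tuberculata	16S	MeTu-16S-F	GGTCTRACGAAAGCAATACT	58	2	230	3
MeTu-16S	Melanoides tuberculata	16S	MeTu-16S-R	GCTTTGCTKGATCTAAAYYT	58	2	230	3
MyLe-COI	Mytilopsis leucophaeata	COI	MyLe-COI-F	GGTTGTAACAACGCACGGTTTAG	66	1	193	0.76
MyLe-COI	Mytilopsis leucophaeata	COI	MyLe-COI-R	CACCTTCTCTGAAAGCCGAGC	66	1	193	0.76
SiWo-COI	Sinanodonta woodiana	COI	SiWo-COI-F	GGGTCAGCCMGGRAGGCTTTTA	68	1	258	0.202
SiWo-COI	Sinanodonta woodiana	COI	SiWo-COI-R	TGTTCACCCTGTACCAACRCCC	68	1	258	0.202
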