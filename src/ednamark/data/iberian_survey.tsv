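site_id	assay	extraction_index	pcr_index	outcome
MR	CoFl-16S	1	1	negative
MR	CoFl-16S	1	2	negative
MR	CoFl-16S	2	1	negative
MR	CoFl-16S	2	2	negative
MR	MeTu-16S	1	1	negative
MR	MeTu-16S	1	2	negative
MR	MeTu-16S	2	1	negative
MR	MeTu-16S	2	2	negative
MR	MyLe-COI	1	1	negative
MR	MyLe-COI	1	2	negative
MR	MyLe-COI	2	1	negative
MR	MyLe-COI	2	2	negative
MR	SiWo-COI	1	1	positive
MR	SiWo-COI	1	2	positive
MR	SiWo-COI	2	1	positive
MR	SiWo-COI	2	2	positive
M1	CoFl-16S	1	1	negative
M1	CoFl-16S	1	2	negative
M1	CoFl-16S	2	1	negative
M1	CoFl-16S	2	2	negative
M1	MeTu-16S	1	1	negative
M1	MeTu-16S	1	2	negative
M1	MeTu-16S	2	1	negative
M1	MeTu-16S	2	2	negative
M1	MyLe-COI	1	1	negative
M1	MyLe-COI	1	2	negative
M1	MyLe-COI	2	1	negative
M1	MyLe-COI	2	2	negative
M1	SiWo-COI	1	1	negative
M1	SiWo-COI	1	2	negative
M1	SiWo-COI	2	1	negative
M1	SiWo-COI	2	2	negative
M2	CoFl-16S	1	1	negative
M2	CoFl-16S	1	2	negative
M2	CoFl-16S	2	1	negative
M2	CoFl-16S	2	2	negative
M2	MeTu-16S	1	1	negative
M2	MeTu-16S	1	2	negative
M2	MeTu-16S	2	1	negative
M2	MeTu-16S	2	2	negative
M2	MyLe-COI	1	1	negative
M2	MyLe-COI	1	2	negative
M2	MyLe-COI	2	1	negative
M2	MyLe-COI	2	2	negative
M2	SiWo-COI	1	1	negative
M2	SiWo-COI	1	2	negative
M2	SiWo-COI	2	1	negative
M2	SiWo-COI	2	2	negative
M3	CoFl-16S	1	1	negative
M3	CoFl-16S	1	2	negative
M3	CoFl-16S	2	1	negative
M3	CoFl-16S	2	2	negative
M3	MeTu-16S	1	1	negative
M3	MeTu-16S	1	2	negative
M3	MeTu-16S	2	1	negative
M3	MeTu-16S	2	2	negative
M3	MyLe-COI	1	1	negative
M3	MyLe-COI	1	2	negative
M3	MyLe-COI	2	1	negative
M3	MyLe-COI	2	2	negative
M3	SiWo-COI	1	1	negative
M3	SiWo-COI	1	2	negative
M3	SiWo-COI	2	1	negative
M3	SiWo-COI	2	2	negative
S1	CoFl-16S	1	1	negative
S1	CoFl-16S	1	2	negative
S1	CoFl-16S	2	1	negative
S1	CoFl-16S	2	2	negative
S1	MeTu-16S	1	1	negative
S1	MeTu-16S	1	2	negative
S1	MeTu-16S	2	1	negative
S1	MeTu-16S	2	2	negative
S1	MyLe-COI	1	1	positive
S1	MyLe-COI	1	2	positive
S1	MyLe-COI	2	1	positive
S1	MyLe-COI	2	2	positive
S1	SiWo-COI	1	1	negative
S1	SiWo-COI	1	2	negative
S1	SiWo-COI	2	1	negative
S1	SiWo-COI	2	2	negative
S2	CoFl-16S	1	1	negative
S2	CoFl-16S	1	2	negative
S2	CoFl-16S	2	1	negative
S2	CoFl-16S	2	2	negative
S2	MeTu-16S	1	1	negative
S2	MeTu-16S	1	2	negative
S2	MeTu-16S	2	1	negative
S2	MeTu-16S	2	2	negative
S2	MyLe-COI	1	1	positive
S2	MyLe-COI	1	2	positive
S2	MyLe-COI	2	1	positive
S2	MyLe-COI	2	2	positive
S2	SiWo-COI	1	1	negative
S2	SiWo-COI	1	2	negative
S2	SiWo-COI	2	1	negative
S2	SiWo-COI	2	2	negative
S3	CoFl-16S	1	1	negative
S3	CoFl-16S	1	2	negative
S3	CoFl-16S	2	1	negative
S3	CoFl-16S	2	2	negative
S3	MeTu-16S	1	1	negative
S3	MeTu-16S	1	2	negative
S3	MeTu-16S	2	1	negative
S3	MeTu-16S	2	2	negative
S3	MyLe-COI	1	1	negative
S3	MyLe-COI	1	2	negative
S3	MyLe-COI	2	1	negative
S3	MyLe-COI	2	2	negative
S3	SiWo-COI	1	1	negative
S3	SiWo-COI	1	2	negative
S3	SiWo-COI	2	1	negative
S3	SiWo-COI	2	2	negative
EL	CoFl-16S	1	1	negative
EL	CoFl-16S	1	2	negative
EL	CoFl-16S	2	1	negative
EL	CoFl-16S	2	2	negative
EL	MeTu-16S	1	1	positive
EL	MeTu-16S	1	2	positive
EL	MeTu-16S	2	1	positive
EL	MeTu-16S	2	2	positive
EL	MyLe-COI	1	1	negative
EL	MyLe-COI	1	2	negative
EL	MyLe-COI	2	1	negative
EL	MyLe-COI	2	2	negative
EL	SiWo-COI	1	1	negative
EL	SiWo-COI	1	2	negative
EL	SiWo-COI	2	1	negative
EL	SiWo-COI	2	2	negative
Z1	CoFl-16S	1	1	positive
Z1	CoFl-16S	1	2	positive
Z1	CoFl-16S	2	1	positive
Z1	CoFl-16S	2	2	positive
Z1	MeTu-16S	1	1	negative
Z1	MeTu-16S	1	2	negative
Z1	MeTu-16S	2	1	negative
Z1	MeTu-16S	2	2	negative
Z1	MyLe-COI	1	1	negative
Z1	MyLe-COI	1	2	negative
Z1	MyLe-COI	2	1	negative
Z1	MyLe-COI	2	2	negative
Z1	SiWo-COI	1	1	negative
Z1	SiWo-COI	1	2	negative
Z1	SiWo-COI	2	1	negative
Z1	SiWo-COI	2	2	negative
Z2	CoFl-16S	1	1	positive
Z2	CoFl-16S	1	2	positive
Z2	CoFl-16S	2	1	positive
Z2	CoFl-16S	2	2	positive
Z2	MeTu-16S	1	1	negative
Z2	MeTu-16S	1	2	negative
Z2	MeTu-16S	2	1	negative
Z2	MeTu-16S	2	2	negative
Z2	MyLe-COI	1	1	negative
Z2	MyLe-COI	1	2	negative
Z2	MyLe-COI	2	1	negative
Z2	MyLe-COI	2	2	negative
Z2	SiWo-COI	1	1	negative
Z2	SiWo-COI	1	2	negative
Z2	SiWo-COI	2	1	negative
Z2	SiWo-COI	2	2	negative
Z3	CoFl-16S	1	1	positive
Z3	CoFl-16S	1	2	positive
Z3	CoFl-16S	2	1	positive
Z3	CoFl-16S	2	2	positive
Z3	MeTu-16S	1	1	negative
Z3	MeTu-16S	1	2	negative
Z3	MeTu-16S	2	1	negative
Z3	MeTu-16S	2	2	negative
Z3	MyLe-COI	1	1	negative
Z3	MyLe-COI	1	2	negative
Z3	MyLe-COI	2	1	negative
Z3	MyLe-COI	2	2	negative
Z3	SiWo-COI	1	1	negative
Z3	SiWo-COI	1	2	negative
Z3	SiWo-COI	2	1	negative
Z3	SiWo-COI	2	2	negative
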