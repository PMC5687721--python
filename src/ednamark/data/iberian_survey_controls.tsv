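control_type	site_id	assay	outcome
universal	MR		positive
universal	M1		positive
universal	M2		positive
universal	M3		positive
universal	S1		positive
universal	S2		positive
universal	S3		positive
universal	EL		positive
universal	Z1		positive
universal	Z2		positive
universal	Z3		positive
extraction_negative		CoFl-16S	negative
pcr_negative		CoFl-16S	negative
extraction_negative		MeTu-16S	negative
pcr_negative		MeTu-16S	negative
extraction_negative		MyLe-COI	negative
pcr_negative		MyLe-COI	negative
extraction_negative		SiWo-COI	negative
pcr_negative		SiWo-COI	negative
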