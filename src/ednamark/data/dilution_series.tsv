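assay	stock_ng_ml	dilution_factor	outcome
CoFl-16S	3750	5	positive
CoFl-16S	3750	10	positive
CoFl-16S	3750	25	positive
CoFl-16S	3750	50	positive
CoFl-16S	3750	100	positive
CoFl-16S	3750	500	positive
CoFl-16S	3750	1000	positive
CoFl-16S	3750	5000	positive
CoFl-16S	3750	10000	positive
CoFl-16S	3750	50000	negative
CoFl-16S	3750	100000	negative
MeTu-16S	3000	5	positive
MeTu-16S	3000	10	positive
MeTu-16S	3000	25	positive
MeTu-16S	3000	50	positive
MeTu-16S	3000	100	positive
MeTu-16S	3000	500	positive
MeTu-16S	3000	1000	positive
MeTu-16S	3000	5000	negative
MeTu-16S	3000	10000	negative
MeTu-16S	3000	50000	negative
MeTu-16S	3000	100000	negative
MyLe-COI	3800	5	positive
MyLe-COI	3800	10	positive
MyLe-COI	3800	25	positive
MyLe-COI	3800	50	positive
MyLe-COI	3800	100	positive
MyLe-COI	3800	500	positive
MyLe-COI	3800	1000	positive
MyLe-COI	3800	5000	positive
MyLe-COI	3800	10000	negative
MyLe-COI	3800	50000	negative
MyLe-COI	3800	100000	negative
SiWo-COI	2020	5	positive
SiWo-COI	2020	10	positive
SiWo-COI	2020	25	positive
SiWo-COI	2020	50	positive
SiWo-COI	2020	100	positive
SiWo-COI	2020	500	positive
SiWo-COI	2020	1000	positive
SiWo-COI	2020	5000	positive
SiWo-COI	2020	10000	positive
SiWo-COI	2020	50000	negative
SiWo-COI	2020	100000	negative
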