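term	semantic_type	in_chv	familiarity
thrombocytosis	Finding	1	0.25
crohn disease	Disease or syndrome	1	0.35
budesonide	Organic chemical	1	0.3
diabetes mellitus	Disease or syndrome	1	0.55
metformin	Organic chemical	1	0.4
cbc	Diagnostic procedure	1	NA
platelet count	Diagnostic procedure	1	NA
gastrointestinal bleeding	Pathologic function	1	NA
hematemesis	Finding	0	NA
epistaxis	Finding	1	0.15
tuberculosis	Disease or syndrome	1	0.6
infectious disease	Disease or syndrome	1	NA
oncologist	other	1	0.7
insulin	Amino acid, peptide, or protein	1	0.65
retinopathy	Disease or syndrome	1	0.3
renal dysfunction	Pathologic function	1	NA
iron	Organic chemical	1	0.9
blood	other	1	0.95
stool	other	1	0.85
cancer	Neoplastic process	1	0.9
prostate	other	1	0.8
weight loss	Finding	1	0.8
vomiting	Finding	1	0.9
fever	Finding	1	0.85
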