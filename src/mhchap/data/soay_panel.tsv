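# Eight MHC class IIa haplotypes of the Soay sheep study population.
# Dash = locus absent (no PCR product from locus-specific primers).
# "/" joins an ambiguity group (alleles identical throughout the assayed
# exon 2, occupying a single chromosomal slot); "," separates distinct
# alleles carried at one locus.
haplotype	DRB1	DQA1	DQA2	DQA2-like	DQB1	DQB2	DQB2-like
A	DRB1*01:01	-	DQA2*10:01:01	DQA2-like*03:01:01	-	DQB2*09:01:01	DQB2-like*03:01:01
B	DRB1*01:02	DQA1*03:01:01	DQA2*01:01:01	-	DQB1*02:01:01	DQB2*04:01:01	-
C	DRB1*03:02	DQA1*Z28420	DQA2*07:01:01	-	DQB1*LN868258	DQB2*AJ238945	-
D	DRB1*10:01	DQA1*03:01:01	DQA2*02:01:01	-	DQB1*07:01:01/DQB1*07:02:01	DQB2-D	-
E	DRB1*13:01	-	DQA2*01:02:01	DQA2-like*01:01:01	-	DQB2*10:01:01	DQB2-like*01:01:01
F	DRB1*22:01	DQA1*03:02:01	DQA2*09:01:02	-	DQB1*AJ23941	DQB2-F	-
G	DRB1*01:01	-	DQA2*01:02:01	DQA2-like*01:01:01	-	DQB2*09:01:01,DQB2*12:01:01	DQB2-like*01:01:01
H	DRB1*22:01	DQA1*04:02:01	DQA2*04:02:01	-	DQB1-H	DQB2*11:01:01	-
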