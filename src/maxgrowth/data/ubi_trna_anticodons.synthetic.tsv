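# SYNTHETIC STAND-IN list of nearly-ubiquitous tRNA anticodons (DNA alphabet).
# Constructed as the Watson-Crick anticodons of commonly preferred codons;
# replace with the published ubi-tRNA anticodon list for production use.
# anticodon	amino_acid	matched_codon
TGC	Ala	GCA
ACG	Arg	CGT
GTT	Asn	AAC
GTC	Asp	GAC
GCA	Cys	TGC
CTG	Gln	CAG
TTC	Glu	GAA
GCC	Gly	GGC
GTG	His	CAC
GAT	Ile	ATC
CAG	Leu	CTG
TTT	Lys	AAA
CAT	Met	ATG
GAA	Phe	TTC
CGG	Pro	CCG
AGA	Ser	TCT
GGT	Thr	ACC
CCA	Trp	TGG
GTA	Tyr	TAC
AAC	Val	GTT
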