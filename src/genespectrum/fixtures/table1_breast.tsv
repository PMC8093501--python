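gene	clingen_category	nccn_category	omim	ghr	genecards	gene_ncbi
ATM	Definitive	Strong	1	1	1	1
BARD1	Definitive	Strong	1	1	1	1
BRCA1	Definitive	Very strong	1	1	1	1
BRCA2	Definitive	Very strong	1	1	1	1
CDH1	Definitive	Strong	1	1	1	1
CHEK2	Definitive	Strong	1	1	1	1
STK11	Definitive	Strong	1	1		
PALB2	Definitive	Strong	1		1	
TP53	Definitive	Strong		1		1
PTEN	Definitive	Strong		1		
NF1		Strong				
RECQL	Moderate					
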