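AlDA1	CATCTGCCG
AlDA2	GGACAG
AlDB1	ATCTGT
AlDB2	AAGACGCT
AlPA1	GAATGCAATA
AlPA2	TAGCAG
AlPB1	ATCCG
AlPB2	CTTAG
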