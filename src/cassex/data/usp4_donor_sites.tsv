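species	group	exon_present	ss6	pwms6	ss7	pwms7
Human	mammal	1	TCAAAGTAAGTGA	8.6625	AGGGGGTAAGAGC	5.0898
Chimpanzee	mammal	1	TCAAAGTAAGTCA	9.0200	AGGGGGTAAGAGC	5.0898
Mouse	mammal	1	TCAAAGTAAGTGA	9.5187	AGGGGGTAAGAAC	5.5747
Rat	mammal	1	TCAAAGTAAGTGA	9.3740	AGGGGGTAAGAAC	5.5747
Cow	mammal	1	TCAAAGTAAGTGA	9.1264	AGGGGGTAAGAGC	5.0898
Dog	mammal	1	TCAAAGTAAGTGA	9.1264	AGGGGGTAAGAGC	5.5361
Shrew	mammal	1	ACAAAGTAAGTGG	9.3351	CGGGGGTAAGCGC	6.5608
Armadillo	mammal	1	CCAAAGTAAGTCA	9.7922	AGGGGGTAAGAGC	5.5361
Opossum	mammal	1	TCCAAGTAAGTGA	9.9648	AGGGGGTAAGAGC	4.6637
Platypus	mammal	1	TCAAAGTAAGGGA	8.3157	CGGGGGTAAGAGC	4.8212
Chicken	bird	1	GCAAAGTAAGAGT	5.6036	AGGGGGTAAGAGC	5.9924
Zebrafish	fish	1	TCAAAGTATGTCC	7.9026	AACAGGTCAGCTT	8.1978
Turtle	reptile	1	ACAAAGTAAGCAT	10.6407	GGGGGGTAAGACC	3.8889
Frog	amphibian	1	ACAAAGTGAGTAT	8.5266	AAAGGGTAACTAT	6.4370
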