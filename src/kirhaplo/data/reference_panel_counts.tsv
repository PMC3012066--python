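haplotype	AFA	ASI	HIS	CAU	total_published
cA01|tA01	52	61	59	60	232
cA01|tB01	5	15	15	9	45
cB01|tB01	2	1	1	6	10
cB02|tA01	6	5	8	15	34
cB01|tA01	14	2	8	4	28
cB02|tB01	2	6	4	1	13
cB03|tA01	2	0	0	0	2
other	13	6	1	1	21
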