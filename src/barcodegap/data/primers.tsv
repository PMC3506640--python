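gene	region	forward_name	forward	reverse_name	reverse	ecoli_start	ecoli_end
16S	V1-V3	27F	AGAGTTTGATCCTGGCTCAG	534R	ATTACCGCGGCTGCTGG	27	534
16S	V2-V4	F101	AGYGGCGIACGGGTGAGTAA	R806	GGACTACARGGTATCTAAT	101	806
16S	V3-V5	357F	CCTACGGGAGGCAGCAG	926R	CCGTCAATTCMTTTRAGT	357	926
16S	V6	F907	AAACTCAAAKGAATTGACGG	R1073	ACGAGCTGACGACARCCATG	907	1073
16S	V6-alternate	L-V6	CAACGCGARGAACCTTACC	R-V6	ACAACACGAGCTGACGAC	985	1078
cpn60	UT	H279	GAIIIIGCIGGIGAYGGIACIACIAC	H280	YKIYKITCICCRAAICCIGGIGCYTT	274	828
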