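chr17	0	10800000	TP53_17p13
chr13	45800000	55300000	RB1_13q14
chr8	116700000	145138636	MYC_8q24
chr1	143200000	155100000	GAIN_1q21
chr1	55300000	61300000	DEL_1p32
chr14	100400000	107043718	IGH_14q32
chr2	83100000	93900000	IGK_2p11
chr22	12200000	25500000	IGL_22q11
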