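#gene_id	name	chrom	start	end	role
BraA07g036130.3C	BrMYBL2.1	A07	25180918	25181774	negative_regulator
BraA09g015240.3C	BrEGL3.1	A09	8904764	8908450	positive_regulator
BraA09g013410.3C	BrEGL3.2	A09	7821182	7824280	positive_regulator
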