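accession	tissue	treatment	same	opposite
GSE37537	whole_body	dietary_restriction	94	106
GSE26724	head_thorax	dietary_restriction	61	33
GSE48145	whole_body	ovoD_mutant	145	85
GSE48145	whole_body	corpora_allata_knockout	45	37
GSE48145	whole_body	ovoD_with_CAKO	146	88
GSE26726	whole_body	dietary_restriction_10d_yw	112	75
GSE26726	whole_body	dietary_restriction_40d_yw	48	29
GSE26726	whole_body	dietary_restriction_10d_CantonS	109	79
GSE26726	whole_body	dietary_restriction_40d_CantonS	86	62
GSE26726	whole_body	p53_knockdown_10d	43	20
GSE26726	whole_body	sir2_overexpression_10d	91	40
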