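AD	default adenocarcinoma (AR-driven) lineage panel; editable	AR	KLK3	KLK2	NKX3-1	TMPRSS2	FOLH1	HOXB13	STEAP1
NE	default neuroendocrine lineage panel; editable	SYP	CHGA	ENO2	ASCL1	INSM1	SOX2	FOXA2	DLL3
DN	default double-negative (AR-/NE-) panel; editable	VIM	ZEB1	SNAI2	ID1	EZH2	NCOA2	MYC
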