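exhaustion	T-cell exhaustion signature (mean-z)	PDCD1	CTLA4	LAG3	HAVCR2	TIGIT	TOX	ENTPD1
PMN_MDSC	polymorphonuclear MDSC signature (mean-z)	S100A8	S100A9	FUT4	CXCR2	CSF3R
M_MDSC	monocytic MDSC signature (mean-z)	CD14	ITGAM	CSF1R	CCR2
immuno_activating	immuno-activating cytokines (mean TPM)	IFNG	TNF	IL12A	IL12B
immuno_suppressive	immuno-suppressive cytokines (mean TPM)	VEGFA	TGFB1	IL6	IL10
cytolytic	cytolytic activity: granzyme B and perforin 1 (mean TPM)	GZMB	PRF1
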