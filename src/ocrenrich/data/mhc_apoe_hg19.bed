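chr6	26000000	34000000	MHC
chr19	44400000	46500000	APOE
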