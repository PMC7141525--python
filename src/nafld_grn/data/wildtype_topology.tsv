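source	target	sign
HNF4A	HNF4A	activation
HNF1A	HNF1A	activation
PPARG	PPARG	activation
SREBF1	SREBF1	activation
HNF1A	HNF4A	activation
HNF4A	HNF1A	activation
SREBF1	PPARG	activation
PPARG	SREBF1	activation
SREBF1	HNF4A	inhibition
HNF1A	PPARG	inhibition
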