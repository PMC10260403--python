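gene	beta
GENE0007	-0.8
GENE0042	-0.5
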