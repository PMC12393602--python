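gene_id
G0007
G0008
G0015
G0017
G0018
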