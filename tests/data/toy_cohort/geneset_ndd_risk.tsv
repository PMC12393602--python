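gene_id
G0009
G0022
G0023
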