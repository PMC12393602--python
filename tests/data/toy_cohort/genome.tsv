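chrom	length
1	1200000
2	1200000
3	1200000
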