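key	value
n_samples	160
n_cases	80
n_controls	80
n_calls_raw	172
n_calls_qualifying	168
n_calls_analysis_grade	137
n_planted_loci	1
seed	20240901
planted_locus_0	2:400000-600000:DUP:0.05:8.0
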