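gene_id	pli
G0001	0.342341
G0002	0.467690
G0003	0.357342
G0004	0.070145
G0005	0.054771
G0006	0.086049
G0007	0.985648
G0008	0.988711
G0009	0.067439
G0010	0.058372
G0011	0.435190
G0012	0.420555
G0013	0.236647
G0014	0.280710
G0015	0.978240
G0016	0.306089
G0017	0.987182
G0018	0.988366
G0019	0.268764
G0020	0.319640
G0021	0.255362
G0022	0.261099
G0023	0.167323
G0024	0.478729
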