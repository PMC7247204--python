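strain	dose_gy	organ	mean_mf_e6	sd_mf_e6	n_animals
WT	0	brain	1.03	0.64	10
WT	10	brain	5.00	1.1	8
scid	0	brain	0.85	0.67	6
scid	10	brain	2.89	1.0	7
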