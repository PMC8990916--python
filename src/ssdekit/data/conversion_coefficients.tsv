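phantom_cm	a	b	d_min_cm	d_max_cm
32	3.704369	0.03671937	6.0	55.0
16	1.874799	0.03871313	6.0	45.0
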