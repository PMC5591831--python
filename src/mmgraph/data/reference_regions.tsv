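modality	region	x_mm	y_mm	z_mm	r1_gamma_mean	r1_gamma_sd	r2_gamma_mean	r2_gamma_sd
eeg	P4	41	-55	37	1.81	0.27	2.03	0.21
eeg	FC5	-56	1	21	1.26	0.31	1.71	0.42
fmri	Right inferior cerebellum	18	-81	-33	1.43	0.32	1.69	0.23
fmri	Left anterior insula	-36	18	2	1.37	0.36	1.63	0.24
fmri	Right medial frontal	0	15	45	1.42	0.24	1.70	0.34
fmri	Right ventral frontal	51	23	8	1.31	0.34	1.58	0.22
fmri	Left dorso-lateral prefrontal	-44	27	33	1.38	0.23	1.73	0.21
fmri	Right inferior parietal lobule	54	-44	43	1.30	0.28	1.69	0.15
fmri	Left parietal	-55	-22	38	1.26	0.28	1.63	0.19
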