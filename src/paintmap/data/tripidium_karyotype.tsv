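chrom_label	long_mean	long_sd	short_mean	short_sd	total_mean	total_sd	ratio_mean	ratio_sd
Chr.1	2.02	0.19	1.56	0.10	3.58	0.19	1.30	0.18
Chr.2	2.03	0.06	1.54	0.10	3.57	0.11	1.32	0.11
Chr.3	2.08	0.21	1.49	0.21	3.57	0.30	1.42	0.24
Chr.4	1.84	0.16	1.29	0.15	3.13	0.22	1.45	0.21
Chr.5	1.76	0.21	1.49	0.13	3.25	0.26	1.19	0.17
Chr.6	1.80	0.90	0.90	0.10	2.69	0.22	2.03	0.37
Chr.7	1.70	0.19	1.39	0.09	3.10	0.24	1.22	0.12
Chr.8	1.40	0.13	1.10	0.14	2.50	0.23	1.29	0.15
Chr.9	1.42	0.16	1.19	0.11	2.61	0.20	1.20	0.18
Chr.10	1.38	0.08	1.21	0.09	2.59	0.12	1.14	0.10
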