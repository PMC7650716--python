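mirna	role	submergence	drought	drought_submergence	submergence_drought
miR156k	responsive	-0.86	1.09	-0.54	1.17
miR159ab	responsive	-1.46	1.06	-1.43	0.55
miR164e	responsive	-0.29	1.20	0.06	1.09
miR166bd	responsive	-2.77	-1.49	-1.95	-0.77
miR167cdeg	responsive	-1.62	-0.33	-1.87	0.71
miR169cr	responsive	-1.05	0.11	-1.60	0.11
miR319b	responsive	-0.66	2.17	-0.41	0.16
miR396cd	responsive	-0.39	1.08	-0.94	0.53
miR398ab	responsive	-1.09	0.05	-1.56	-0.58
miR398b	responsive	-0.69	0.29	-1.92	-0.57
miR408	responsive	-1.78	-1.76	-0.88	0.55
miR408b	responsive	-2.57	0.17	-0.43	-0.87
miR528ab	responsive	-2.22	-0.57	-3.16	-0.99
miR166c	constitutive	-0.21	-0.19	-0.27	-0.19
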