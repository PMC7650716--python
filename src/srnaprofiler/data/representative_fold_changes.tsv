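mirna	role	maize_submergence	maize_drought	teosinte_submergence	teosinte_drought
miR156k	responsive	-2.94	-2.99	-0.86	1.09
miR159ab	responsive	-2.17	0.80	-1.46	1.06
miR164e	responsive	-4.24	-1.49	-0.29	1.20
miR166bd	responsive	-4.39	-3.79	-2.77	-1.49
miR167cdeg	responsive	-2.99	-2.48	-1.62	-0.33
miR169cr	responsive	-3.13	-0.95	-1.05	0.11
miR319b	responsive	-0.75	0.80	-0.66	2.17
miR396cd	responsive	-1.04	-0.17	-0.39	1.08
miR398ab	responsive	-0.38	-0.29	-1.09	0.05
miR398b	responsive	-2.83	-0.94	-0.69	0.29
miR408	responsive	-1.34	-0.51	-1.78	-1.76
miR408b	responsive	-2.14	-0.89	-2.57	0.17
miR528ab	responsive	-1.30	-1.65	-2.22	-0.57
miR166c	constitutive	0.00	-0.01	-0.21	-0.19
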