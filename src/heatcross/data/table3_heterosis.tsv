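hybrid	TNF	FW	YP	TSSC	TA	TSSC/TA
17H14	-1.37	-21.44	8.00	7.16	14.41	-6.02
17H25	85.10	9.34	127.76	7.03	20.13	-15.17
17H36	-30.35	-10.65	-24.21	7.50	-0.98	-2.93
17H37	49.28	15.08	76.14	2.22	-12.74	15.17
17H39	128.27	27.05	183.09	-1.12	-16.92	16.92
17H56	69.83	22.42	120.76	5.49	-17.80	35.21
17H57	136.32	18.49	192.65	3.63	-12.12	20.04
18H13	-11.71	8.12	-5.52	5.88	16.54	-13.52
18H17	79.27	4.99	75.77	12.48	32.23	-16.01
18H48	9.60	12.70	22.04	9.45	2.72	18.94
18H56	80.34	13.33	126.21	0.87	-6.18	9.95
18H57	-4.79	-31.29	-8.24	1.32	-20.79	22.71
18H59	-6.97	-24.50	47.79	7.52	20.64	-8.63
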