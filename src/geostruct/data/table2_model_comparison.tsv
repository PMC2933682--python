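variant	group	description	beta0	beta0_sig	beta1	beta1_sig	beta2	beta2_lo	beta2_hi	beta2_sig	beta3	beta3_lo	beta3_hi	beta3_sig	dic
1	baseline	Random	-0.17	0											5605
2	gini	Log	-0.18	1	-2.71	1	1.14	-0.2	2.37	0					5601
3	gini	Log (deterministic)	-0.19	1	-2.74	1	1.28	0.44	2.11	1					5600
4	gini	Linear	-0.18	1	0.06	1	0.11	-0.02	0.22	0					5601
5	gini	Linear (deterministic)	-0.19	1	0.06	1	0.12	0.02	0.22	1					5600
6	size	Log	-0.18	1	-2.43	1					0.19	-0.04	0.42	0	5601
7	size	Log (deterministic)	-0.18	0	-2.40	1					0.18	0.05	0.32	1	5601
8	size	Linear	-0.14	0	0.09	1					0.02	-0.00	0.05	0	5602
9	size	Linear (deterministic)	-0.22	1	0.09	1					0.02	0.00	0.04	1	5600
10	combined	Log	-0.19	0	-2.70	1	0.85	-0.57	2.17	0	0.14	-0.10	0.38	0	5601
11	combined	Linear	-0.16	1	0.06	1	0.09	-0.06	0.21	0	0.01	-0.01	0.04	0	5601
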