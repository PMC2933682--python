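band	label	proportion	rate
0	0	0.016	0.00900
1	1-4	0.060	0.00045
2	5-9	0.075	0.00022
3	10-14	0.078	0.00022
4	15-19	0.084	0.00080
5	20-24	0.089	0.00110
6	25-29	0.088	0.00120
7	30-34	0.085	0.00140
8	35-39	0.083	0.00180
9	40-44	0.080	0.00280
10	45-49	0.072	0.00450
11	50-54	0.067	0.00750
12	55-59	0.063	0.01200
13	60-64	0.060	0.01900
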