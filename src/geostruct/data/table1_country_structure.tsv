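country	n_regions	mean_pop	min_pop	min_region	max_pop	max_region	gini	sigma_u_model1
Austria	9	388511	116581	Burgenland	630930	Lower Austria	0.30	0.18
Bulgaria	9	441315	260422	Mikhaylovgrad	544456	Plovdiv	0.10	0.05
Czech Rep.	8	590147	309375	Jihocesky	894204	Jihomoravsky	0.19	0.11
Denmark	15	154584	19057	Bornholm	262859	Arhus	0.25	0.14
Finland	12	190464	10549	Ahvenanmaa	549665	Uusimaa	0.39	0.12
France	22	1171828	106513	Corsica	4796173	Ile de France	0.37	0.11
Germany	16	2255913	286632	Bremen	7519917	North Rhine-Westphalia	0.44	0.18
Greece	13	354070	79930	Ionian Islands	1475350	Attica	0.46	0.13
Hungary	20	232590	96365	Nograd	821739	Budapest	0.29	0.09
Italy	20	1275911	50272	Valle d'Aosta	3803059	Lombardy	0.43	0.09
Netherlands	12	579653	105133	Flevoland	1429211	Zuid-Holland	0.40	0.05
Norway	18	106327	34522	Finnmark	373730	Oslo og Akershus	0.32	0.12
Poland	49	363065	109241	Chelm	1855334	Katowice	0.31	0.09
Romania	41	264735	107245	Covasna	1006544	Bucharest	0.24	0.09
Russian Fed.	79	850337	80665	Chukotka	3686473	Moscow (city)	0.39	0.10
Spain	18	988100	57000	Ceutay Melilla	3088000	Andalusia	0.47	0.12
Sweden	24	160028	24045	Gotland	709982	Stockholm	0.34	0.09
Switzerland	26	117639	6046	Appenzell-Inner Rhoden	499548	Zurich	0.51	0.08
UK	56	462425	48617	Isle of Wight	2970235	Greater London	0.42	0.13
Ukraine	26	878529	399913	Chernivtsi	2293997	Donetsk	0.25	0.08
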