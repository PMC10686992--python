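name	n_nodes	f0	E	E00	E01	E11	r_printed	r_adj_printed
APS (2000)	8285	0.11	9071	126	1539	7406	0.05	0.11
GitHub	311755	0.06	1537570	7432	149069	1381069	0.04	0.15
DBLP (2010)	170984	0.21	322052	17468	91738	212846	0.10	0.14
DBLP (2000)	54966	0.18	72369	3123	18101	51145	0.11	0.16
DBLP (1990)	13764	0.15	12178	384	2701	9093	0.09	0.16
DBLP (1980)	2664	0.11	1765	24	274	1467	0.06	0.16
INFORMS (2010)	1426	0.16	1009	34	247	728	0.07	0.12
SocioPatterns 4	180	0.27	2220	182	762	1276	0.09	0.12
SocioPatterns 5	327	0.44	5818	1471	2348	1999	0.19	0.19
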