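source	factor	Q	sites	pair2	pair7	pair9	pair14	total
HAIB-K562	GABP	0.23	593	0.087	0.126	0.254	0.458	0.925
HAIB-K562	NRSF	0.85	1714	0.261	0.254	0.264	0.069	0.849
HAIB-K562	SRF	0.76	280	0.424	0.098	0.119	0.112	0.752
YALE-GM128	NFKB	0.85	2267	0.336	0.169	0.132	0.021	0.658
YALE-HCT116	TCF7L2	0.91	3075	0.280	0.116	0.057	0.012	0.466
YALE-HepG2	SREBP1	0.57	2844	0.283	0.132	0.135	0.065	0.615
YALE-K562b	GATA1	0.89	3011	0.330	0.231	0.139	0.021	0.721
YALE-K562b	TR4	0.35	191	0.144	0.162	0.322	0.110	0.738
YALE-K562b	ZNF263	0.80	4079	0.051	0.221	0.501	0.073	0.845
YALE-K562	cFos	0.94	3523	0.290	0.190	0.107	0.011	0.598
YALE-K562	Max	0.77	2453	0.237	0.121	0.193	0.065	0.615
YALE-K562	NF-E2	0.93	4380	0.275	0.152	0.086	0.011	0.524
YALE-NT2D1	YY1	0.61	1804	0.338	0.203	0.189	0.099	0.828
YALE-K562-Ia30	STAT1	0.86	898	0.414	0.111	0.067	0.019	0.611
ORegAnno	CTCF	0.90	4368	0.212	0.192	0.363	0.134	0.901
TRANSFAC	sp1	0.41	281	0.063	0.151	0.529	0.206	0.949
TRANSFAC	p53	0.95	579	0.271	0.210	0.075	0.004	0.560
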