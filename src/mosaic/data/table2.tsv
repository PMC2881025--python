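source	factor	P	sites	pair2	pair7	pair9	pair14	total
HAIB-K562	GABP	0.71	2557	0.054	0.035	0.113	0.774	0.976
HAIB-K562	NRSF	0.74	2006	0.236	0.231	0.254	0.142	0.862
HAIB-K562	SRF	0.64	367	0.370	0.083	0.111	0.229	0.794
YALE-GM128	NFKB	0.50	2653	0.322	0.156	0.139	0.069	0.686
YALE-HCT116	TCF7L2	0.50	3386	0.281	0.111	0.060	0.030	0.483
YALE-HepG2	SREBP1	0.50	4958	0.237	0.092	0.137	0.276	0.742
YALE-K562b	GATA1	0.52	3367	0.322	0.221	0.146	0.048	0.736
YALE-K562b	TR4	0.51	541	0.144	0.083	0.216	0.426	0.870
YALE-K562b	ZNF263	0.64	5098	0.049	0.194	0.466	0.147	0.856
YALE-K562	cFos	0.53	3746	0.287	0.186	0.111	0.018	0.603
YALE-K562	Max	0.60	3176	0.210	0.100	0.180	0.185	0.675
YALE-K562	NF-E2	0.81	4700	0.273	0.149	0.088	0.026	0.536
YALE-NT2D1	YY1	0.50	2967	0.252	0.135	0.157	0.333	0.876
YALE-K562-Ia30	STAT1	0.50	1039	0.398	0.104	0.077	0.059	0.638
ORegAnno	CTCF	1.00	4858	0.202	0.181	0.353	0.169	0.905
TRANSFAC	sp1	0.62	693	0.045	0.075	0.332	0.512	0.966
TRANSFAC	p53	0.91	608	0.266	0.203	0.081	0.021	0.571
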