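source	factor	Q	sites	pair2	pair7	pair9	pair14	total
HAIB-K562	GABP	0.77	1964	0.045	0.007	0.071	0.869	0.991
HAIB-K562	NRSF	0.15	292	0.091	0.091	0.192	0.567	0.940
HAIB-K562	SRF	0.24	87	0.197	0.035	0.087	0.609	0.928
YALE-GM128	NFKB	0.15	386	0.238	0.081	0.184	0.347	0.850
YALE-HCT116	TCF7L2	0.09	311	0.295	0.062	0.089	0.207	0.652
YALE-HepG2	SREBP1	0.43	2114	0.174	0.036	0.141	0.560	0.911
YALE-K562b	GATA1	0.11	356	0.256	0.132	0.201	0.276	0.865
YALE-K562b	TR4	0.65	350	0.145	0.040	0.158	0.599	0.943
YALE-K562b	ZNF263	0.20	1019	0.041	0.089	0.329	0.443	0.902
YALE-K562	cFos	0.06	223	0.242	0.137	0.176	0.133	0.688
YALE-K562	Max	0.23	723	0.121	0.029	0.136	0.592	0.877
YALE-K562	NF-E2	0.07	320	0.249	0.106	0.120	0.225	0.699
YALE-NT2D1	YY1	0.39	1163	0.119	0.029	0.107	0.696	0.951
YALE-K562-Ia30	STAT1	0.14	141	0.298	0.061	0.140	0.313	0.812
ORegAnno	CTCF	0.10	490	0.110	0.081	0.258	0.486	0.935
TRANSFAC	sp1	0.59	412	0.033	0.024	0.198	0.722	0.977
TRANSFAC	p53	0.05	29	0.166	0.062	0.194	0.365	0.787
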