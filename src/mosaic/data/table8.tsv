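factor	pair2	pair7	pair9	pair14	total
GABP	0.133	0.102	0.058	0.021	0.314
NRSF	0.176	0.148	0.096	0.011	0.430
SRF	0.131	0.033	0.009	0.001	0.173
NFKB	0.211	0.108	0.058	0.008	0.385
TCF7L2	0.125	0.039	0.009	0.001	0.175
SREBP1	0.198	0.101	0.074	0.014	0.387
GATA1	0.079	0.027	0.006	0.001	0.112
TR4	0.180	0.097	0.046	0.005	0.328
ZNF263	0.055	0.099	0.052	0.010	0.216
cFos	0.183	0.094	0.042	0.002	0.322
Max	0.141	0.079	0.060	0.010	0.290
NF-E2	0.159	0.090	0.037	0.002	0.288
YY1	0.111	0.045	0.016	0.002	0.174
STAT1	0.160	0.039	0.012	0.002	0.213
CTCF	0.159	0.168	0.164	0.041	0.532
sp1	0.082	0.152	0.182	0.074	0.491
p53	0.182	0.126	0.086	0.013	0.406
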