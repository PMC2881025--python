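factor	cell_group	value
GABP	GM128	0.991
NRSF	GM128	0.844
SRF	GM128	0.851
JunD	GM128	0.293
NFKB	GM128	0.686
GABP	K562	0.976
NRSF	K562	0.862
SRF	K562	0.794
cFos	K562	0.603
Max	K562	0.675
STAT1	K562	0.638
TR4	K562	0.870
GATA1	K562	0.736
NF-E2	K562	0.536
ZNF263	K562	0.856
cFos	Other	0.475
SREBP1	Other	0.742
STAT1	Other	0.519
TR4	Other	0.871
TCF7L2	Other	0.483
YY1	Other	0.876
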