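factor	n_all	n_lowtag	ratio	prop_all	prop_lowtag
GATA1	3367	1681	0.499	0.736	0.703
TR4	541	247	0.457	0.870	0.860
ZNF263	5098	3297	0.647	0.856	0.835
cFos	3746	1834	0.490	0.603	0.561
Max	3176	1382	0.435	0.675	0.614
NF-E2	4700	2322	0.494	0.536	0.489
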