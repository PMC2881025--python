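row	pair2	pair7	pair9	pair14	total
genome	0.134	0.071	0.042	0.009	0.256
model	0.134	0.069	0.042	0.009	0.255
promoter	0.170	0.069	0.128	0.233	0.600
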