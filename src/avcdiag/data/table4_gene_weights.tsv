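gene	hidden1	hidden2	hidden3	hidden4	hidden5	output1	output2
CXCL16	1.4422024	0.8067851	-1.2517474	0.81237475	-1.06361	0.1194611	-0.82155472
S100A9	-0.1110034	-0.4236217	0.4201573	-0.02445162	1.550808	0.2818231	0.29068938
GPM6A	-0.3588348	2.3986261	0.848421	-1.39610883	10.063427	1.0300879	-0.63177691
BEX2	1.0788502	0.6817263	-0.4659392	0.52948785	9.040834	0.5961824	0.66712552
SCARA5	-1.0053437	-0.3655945	1.1181273	-0.65628306	9.616735	-1.1183066	1.10673166
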