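gene	auc_merged	auc_validation
CXCL16	0.953	0.861
GPM6A	0.897	0.944
BEX2	0.867	0.861
S100A9	0.897	0.875
SCARA5	0.887	0.931
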