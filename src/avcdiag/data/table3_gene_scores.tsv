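sample	CXCL16	S100A9	GPM6A	BEX2	SCARA5
GSM317342_Normal	0	1	0	0	0
GSM317343_Normal	0	0	0	0	0
GSM317344_Normal	0	0	0	0	0
GSM317345_Normal	0	0	0	0	0
GSM317346_Normal	0	0	0	0	0
GSM377368_Normal	0	0	0	0	0
GSM377369_Normal	1	0	0	0	0
GSM377370_Normal	0	0	0	0	0
GSM377371_Normal	0	0	0	0	1
GSM377372_Normal	0	0	0	0	1
GSM1246204_Normal	0	0	1	0	0
GSM1246205_Normal	0	0	0	0	0
GSM1246206_Normal	0	0	0	1	0
GSM1246207_Normal	0	0	0	0	0
GSM1246208_Normal	0	0	1	0	0
GSM317347_AVC	1	1	1	1	0
GSM317348_AVC	1	1	1	1	1
GSM317349_AVC	1	1	1	1	1
GSM317350_AVC	1	1	1	1	1
GSM317351_AVC	1	1	1	1	1
GSM377373_AVC	1	1	0	1	1
GSM377374_AVC	1	1	1	1	1
GSM377375_AVC	1	1	0	1	1
GSM377376_AVC	1	1	1	1	1
GSM377377_AVC	1	0	1	1	1
GSM1246209_AVC	0	0	1	1	0
GSM1246210_AVC	0	0	0	1	1
GSM1246211_AVC	0	0	0	0	0
GSM1246212_AVC	0	1	1	1	0
GSM1246213_AVC	1	1	1	1	1
GSM1246214_AVC	1	1	1	0	1
GSM1246215_AVC	1	1	1	0	1
GSM1246216_AVC	1	1	1	1	1
GSM1246217_AVC	1	1	1	1	1
GSM1246218_AVC	1	1	1	1	1
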