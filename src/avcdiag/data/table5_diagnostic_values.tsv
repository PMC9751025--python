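sample	value_normal	value_disease
GSM317342_Normal	0.94618326	0.056753254
GSM317343_Normal	0.904296846	0.097606317
GSM317344_Normal	0.904296846	0.097606317
GSM317345_Normal	0.904296846	0.097606317
GSM317346_Normal	0.904296846	0.097606317
GSM377368_Normal	0.904296846	0.097606317
GSM377369_Normal	0.973335408	0.029453828
GSM377370_Normal	0.904296846	0.097606317
GSM377371_Normal	0.982576352	0.001961258
GSM377372_Normal	0.982576352	0.001961258
GSM1246204_Normal	0.993381143	0.002593156
GSM1246205_Normal	0.904296846	0.097606317
GSM1246206_Normal	0.98247582	0.024367009
GSM1246207_Normal	0.904296846	0.097606317
GSM1246208_Normal	0.993381143	0.002593156
GSM317347_AVC	0.019810466	1.001116247
GSM317348_AVC	0.004836848	0.995356568
GSM317349_AVC	0.004836848	0.995356568
GSM317350_AVC	0.004836848	0.995356568
GSM317351_AVC	0.004836848	0.995356568
GSM377373_AVC	-0.007721178	0.994428405
GSM377374_AVC	0.004836848	0.995356568
GSM377375_AVC	-0.007721178	0.994428405
GSM377376_AVC	0.004836848	0.995356568
GSM377377_AVC	-0.050916168	1.037641252
GSM1246209_AVC	-0.001847649	0.995498191
GSM1246210_AVC	0.010441263	1.007113243
GSM1246211_AVC	0.904296846	0.097606317
GSM1246212_AVC	-0.004724825	1.005070695
GSM1246213_AVC	0.004836848	0.995356568
GSM1246214_AVC	-0.003228033	1.003823674
GSM1246215_AVC	-0.003228033	1.003823674
GSM1246216_AVC	0.004836848	0.995356568
GSM1246217_AVC	0.004836848	0.995356568
GSM1246218_AVC	0.004836848	0.995356568
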