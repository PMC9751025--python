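group	predicted_normal	predicted_avc	accuracy
Normal	15	0	1
AVC	1	19	0.95
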