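sample_id	b1	b2	f1
ROV1_0-5cm	120	30	55
ROV1_10-15cm	80	0	200
ROV1_25-30cm	60	10	90
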