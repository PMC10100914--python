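sample_id	site	depth_top_cm	depth_bottom_cm	methane	sulfate	sulfide	dic	seep_status
ROV1_0-5cm	ROV1	0	5	0.4	27.1	0.3	5.2	seep
ROV1_10-15cm	ROV1	10	15	4.8	14.0	1.9	6.1	seep
ROV1_25-30cm	ROV1	25	30	0.9	8.2	0.7	7.4	seep
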