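quantity	baseline	treatment	direction	printed_change
gaze_targeting_sigma_mm	0.39	0.23	lower	41.0
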