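subscale	baseline_mean	treatment_mean	printed_change
mental_demand	84	65	-22.6
physical_demand	85	70	-17.6
temporal_demand	75	64	-14.7
performance	60	75	25.0
effort	72	58	-19.4
frustration	52	35	-32.7
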