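metric	direction	baseline_mean	baseline_sd	treatment_mean	treatment_sd	t_value	n	printed_improvement	printed_d
tasks_completed	higher	3.2	0.6	5.3	0.8	6.84	8	65.6	2.42
spatial_error_mm	lower	0.39	0.07	0.27	0.04	5.12	8	30.8	1.81
movement_efficiency	higher	68.4	5.2	82.8	3.1	7.93	8	21.1	2.80
cognitive_load	lower	72.1	6.8	53.5	5.5		8	25.8	
task_success	higher	88.8	4.1	95.6	2.9	4.21	8	7.7	1.49
control_precision	higher	6.4	0.8	8.1	0.6	5.67	8	26.6	2.00
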