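run	read_set	n_reads	total_length_bp	mean_length_bp	min_length_bp	max_length_bp
run1	raw	1312317	408000000	310.9	40	698
run2	raw	1197626	430800000	359.7	40	837
run1	filtered	955919	278200000	294.5	46	552
run2	filtered	848247	286700000	338.0	40	837
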