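read_set	n_reads
filtered	1804166
mapped	1515232
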