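parameter	value
max_iterations	300
population_size	100
chromosome_length	55
mutation_rate	0.09
crossover_proportion	1
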