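variable	lo	q1	q2	q3	hi	orientation
degree_impact	0	0.044118	0.11111	0.213095	0.4918	ascending
betweenness_impact	0	0	0	0.02748	0.17737	ascending
closeness_impact	0.062116	0.0994065	0.13354	0.21584	0.67273	ascending
fdr	4.3423e-27	2.41705e-05	0.0092785	0.0282315	0.046353	descending
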