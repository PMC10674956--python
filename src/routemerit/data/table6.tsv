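variable	weak_lo	q1	q2	q3	hi
w1	-1	0.040625	0.178125	0.346875	1
w2	-1	0.005215122	0.035244476	0.114987363	1
w3	-1	0.036363636	0.090909091	0.145454545	1
w4	-1	0.005028148	0.046520343	0.093742947	1
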