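metabolite	w1	w2	w3	w4	merit
Maltotriose	0.059375	0.012879969	-1	-1	12.33015695
L-Glutamic acid	0.95625	0.892826812	0.090909091	0.043457267	42.4297409
Pyruvic acid	0.778125	0.558492981	0.272727273	0.088754688	88.06311429
L-Tryptophan	0.296875	0.107651537	0.109090909	0.109603133	62.5
Citric acid	0.45	0.170635833	0.181818182	0.137017563	90.33333333
L-Alanine	0.39375	0.112928955	0.218181818	0.093742947	87.32827717
L-Serine	0.36875	0.084920841	0.127272727	0.045147312	62.5
Betaine	0.15625	0.027372191	0.090909091	0.048277571	42.63825352
Dimethyl sulfone	0.021875	0.000196837	-1	-1	11.6245581
L-Arginine	0.371875	0.131651201	0.290909091	0.14684817	89.35621737
Sphinganine	0.06875	0.015722582	-1	-1	11.6568779
L-Glutamine	0.371875	0.075654603	0.109090909	0.047897573	62.5
L-Tyrosine	0.25	0.068912558	0.090909091	0.037760448	42.4297409
Cholesterol sulfate	0.003125	0	0.418181818	0.475029838	90.25525526
Sucrose	0.178125	0.06483723	0.018181818	0	12.90686029
L-Phenylalanine	0.28125	0.049343156	0.109090909	0.091631965	62.5
L-Cysteine	0.4125	0.143670141	0.090909091	0.080663464	62.5
L-Aspartate-semialdehyde	0.040625	0.0000506488	-1	-1	13.82051282
L-Methionine	0.334375	0.075768988	0.181818182	0.20829445	86.56442358
Creatine	0.1	0.016946398	0.090909091	0.070195678	42.4297409
L-Cystine	0.00625	0	0.127272727	0.041291699	62.5
L-Lysine	0.403125	0.136364416	0.272727273	0.147600818	90.33333333
L-Isoleucine	0.2	0.009885279	0.127272727	0.046520343	44.40997593
Phytosphingosine	0.034375	0.005215122	-1	-1	13.61538462
Adenosine	0.346875	0.119206393	0.054545455	0.0280831	37.5
L-Valine	0.2375	0.020285683	0.145454545	0.068937066	62.5
Glycine	0.4875	0.217186109	0.363636364	0.259194216	90.33333333
L-Leucine	0.28125	0.039149797	0.145454545	0.080064075	62.5
cis-Aconitic acid	0.121875	0.018639401	0.054545455	0.01249794	37.5
Hypotaurine	0.03125	0.000358991	-1	-1	13.08960132
S-Adenosylhomocysteine	0.571875	0.575112844	0.036363636	0.005028148	37.5
L-Aspartic acid	0.359375	0.114987363	0.054545455	0.013255836	37.5
Glutathione	0.296875	0.105460029	0.072727273	0.085964538	62.5
Arachidonic acid	0.228125	0.167812851	0.036363636	0.027691555	37.5
Adenine	0.3	0.12548383	-1	-1	11.49545672
Urea	0.153125	0.059641216	0.090909091	0.011850264	42.4297409
Serotonin	0.3375	0.226082231	0.072727273	0.062262961	54.87490171
Taurine	0.153125	0.047879708	0.090909091	0.077994031	62.5
L-Lactic acid	0.1	0.013350728	1	1	89.44287908
p-Hydroxyphenylacetic acid	0.028125	0.000479396	0.054545455	0.035107811	37.5
Inosine	0.153125	0.021684479	0.054545455	0.029713312	37.5
SM(d18:1/18:0)	0.040625	0.014353102	-1	-1	13.82051282
Hypoxanthine	0.175	0.029327862	0.090909091	0.108400157	62.5
Dopaquinone	0.01875	0.000234529	-1	-1	11.19413764
L-Proline	0.2125	0.042078003	0.2	0.10544835	87.16355188
L-Histidine	0.23125	0.035244476	0.127272727	0.048363647	53.99094217
Guanine	0.165625	0.023106832	0.018181818	0	11.96511859
Cytidine	0.134375	0.02976407	0.018181818	0	11.41056611
Glycerol	1	1	0.109090909	0.169397158	89.55878284
Calcium	-1	-1	0.327272727	0.318269183	90.33333333
Acetoacetic acid	-1	-1	0.127272727	0.064575489	62.5
Formic acid	-1	-1	0.018181818	0	11.41056611
Zinc (II) ion	-1	-1	0.072727273	0.025154387	37.5
Acetic acid	-1	-1	0.054545455	0.012651199	37.5
Cortisol	-1	-1	0.418181818	0.65988514	90.33333333
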