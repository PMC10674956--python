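metabolite
L-Leucine
Inosine
L-Glutamic Acid
L-Aspartate
Zinc (II) ion
SM(d18:1/18:0)
L-Alanine
L-Cystine
cis-Aconitic acid
Dopaquinone
L-Serine
L-Lysine
L-Aspartic acid
L-Histidine
Betaine
Adenosine
Glutathione
Cytidine
L-Arginine
L-Valine
Urea
Glycerol
L-Glutamine
Glycine
Taurine
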