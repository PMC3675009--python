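family,n_structures,n_sequences,n_annotated
AGC,171,19,6
CAMK,231,34,13
CK1,20,6,2
CMGC,500,33,16
Other,114,18,5
STE,55,17,11
TK,445,47,35
TKL,58,9,6
Unclassified,364,75,43
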