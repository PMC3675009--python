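{
 "n_structures": 1958,
 "n_unique_sequences": 208,
 "n_annotated_structures": 1281,
 "n_annotated_sequences": 137,
 "n_compounds": 38,
 "n_binding_site_positions": 27
}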