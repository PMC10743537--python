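species,conc,D,sigma
ligand_obs,0.60,0.87,0.05
dna_obs,0.60,0.71,0.05
ligand_free,0.05,2.31,0.10
dna_free,0.60,0.75,0.05
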