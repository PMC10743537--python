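species,conc,D,sigma
1,0.78,1.78,0.05
1,0.59,1.81,0.10
1,0.10,1.97,0.10
1,0.05,2.12,0.10
2,1.06,1.97,0.05
2,0.05,2.31,0.10
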