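unit,class,free,complex
19-CH3,ligand,0.976,0.952
23-CH3,ligand,1.576,1.278
18-CH2,ligand,2.007,1.913
22-CH2a,ligand,3.200,2.821
22-CH2b,ligand,3.279,2.949
24-CH2a,ligand,3.672,3.546
24-CH2b,ligand,3.926,3.671
17-CH2a,ligand,5.437,5.325
17-CH2b,ligand,5.510,5.400
5-CH,ligand,6.117,5.780
11-CH,ligand,7.253,6.881
9-CH,ligand,7.462,7.184
14-CH,ligand,7.243,7.012
12-CH,ligand,7.330,7.167
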