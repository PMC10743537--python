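unit,class,free,complex
19-CH3,ligand,1.017,0.968
23-CH3,ligand,1.393,1.200
18-CH2,ligand,2.048,1.916
22-CH2a,ligand,3.126,2.647
22-CH2b,ligand,3.186,2.919
24-CH2a,ligand,4.007,3.759
24-CH2b,ligand,4.103,3.759
17-CH2a,ligand,5.454,5.306
17-CH2b,ligand,5.662,5.498
5-CH,ligand,6.133,5.738
11-CH,ligand,7.280,6.955
9-CH,ligand,7.359,6.961
14-CH,ligand,7.384,7.132
12-CH,ligand,7.660,7.225
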