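unit,class,free,complex
G1,H6/H8,8.099,8.099
C2,H6/H8,7.421,7.422
G3,H6/H8,7.984,7.980
T4,H6/H8,7.311,7.306
T5,H6/H8,7.464,7.465
G6,H6/H8,7.672,7.652
T7,H6/H8,7.592,7.562
C8,H6/H8,7.494,7.491
G9,H6/H8,7.963,7.963
C10,H6/H8,7.603,7.603
G11,H6/H8,8.099,8.099
C12,H6/H8,7.396,7.393
G13,H6/H8,7.946,7.941
A14,H6/H8,8.177,8.170
C15,H6/H8,7.177,7.188
A16,H6/H8,8.053,8.073
A17,H6/H8,8.192,8.197
C18,H6/H8,7.182,7.184
G19,H6/H8,7.895,7.893
C20,H6/H8,7.575,7.575
G1,H1',6.022,6.022
C2,H1',5.663,5.666
G3,H1',6.110,6.099
T4,H1',6.095,6.090
T5,H1',6.215,6.151
G6,H1',5.830,5.795
T7,H1',6.093,6.0922
C8,H1',5.766,5.763
G9,H1',5.904,5.904
C10,H1',6.238,6.238
G11,H1',6.022,6.022
C12,H1',5.633,5.633
G13,H1',5.690,5.693
A14,H1',6.261,6.257
C15,H1',5.560,5.610
A16,H1',5.826,5.807
A17,H1',6.156,6.150
C18,H1',5.604,5.602
G19,H1',5.904,5.904
C20,H1',6.226,6.226
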