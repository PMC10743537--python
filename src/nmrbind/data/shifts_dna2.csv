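unit,class,free,complex
G1,H6/H8,8.099,8.099
C2,H6/H8,7.421,7.418
G3,H6/H8,7.984,7.974
T4,H6/H8,7.311,7.298
T5,H6/H8,7.464,7.458
G6,H6/H8,7.672,7.694
T7,H6/H8,7.592,7.545
C8,H6/H8,7.494,7.486
G9,H6/H8,7.963,7.963
C10,H6/H8,7.603,7.603
G11,H6/H8,8.099,8.099
C12,H6/H8,7.396,7.394
G13,H6/H8,7.946,7.940
A14,H6/H8,8.177,8.155
C15,H6/H8,7.177,7.166
A16,H6/H8,8.053,8.081
A17,H6/H8,8.192,8.189
C18,H6/H8,7.182,7.182
G19,H6/H8,7.895,7.893
C20,H6/H8,7.575,7.575
G1,H1',6.022,6.017
C2,H1',5.663,5.663
G3,H1',6.110,6.088
T4,H1',6.095,6.082
T5,H1',6.215,6.184
G6,H1',5.830,5.736
T7,H1',6.093,6.080
C8,H1',5.766,5.756
G9,H1',5.904,5.897
C10,H1',6.238,6.238
G11,H1',6.022,6.016
C12,H1',5.633,5.633
G13,H1',5.690,5.690
A14,H1',6.261,6.241
C15,H1',5.560,5.628
A16,H1',5.826,5.779
A17,H1',6.156,6.140
C18,H1',5.604,5.602
G19,H1',5.904,5.897
C20,H1',6.226,6.226
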