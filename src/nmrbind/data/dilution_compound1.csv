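conc,H12,H9,H11,H23,H5,H24a,H24b,H26/H27,H14,H17a,H17b,H18,H19
0.013,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
0.027,8.9,7.2,22.8,-10.8,25.0,25.1,24.6,-4.4,30.7,5.5,8.2,2.8,3.1
0.053,27.8,19.6,48.6,-21.1,54.2,49.2,49.2,-7.4,61.7,11.3,16.96,6.5,6.4
0.099,39.9,31.7,71.4,-31.1,79.3,71.1,73.8,-11.9,94.2,17.05,24.93,9.9,9.8
0.199,56.8,41.9,94.2,-40.7,99.2,92.4,96.8,-17.7,120.0,21.46,32.3,11.9,11.5
0.349,114.2,49.2,112.2,-50.8,112.1,99.4,113.6,-20.8,144.52,27.5,41.0,15.8,14.8
0.543,142.3,55.3,130.9,-55.5,124.6,118.1,128.5,-23.0,164.2,30.37,46.58,16.2,16.0
0.789,185.0,70.5,149.8,-56.5,140.2,121.2,139.6,-26.6,180.3,34.7,52.0,19.8,18.0
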