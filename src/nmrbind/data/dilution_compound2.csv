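conc,H12,H9,H11,H22,H23,H5,H24a,H25/H28,H14,H17a,H19
0.012,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0,0.0
0.024,10.5,8.3,7.3,0.0,2.0,19.2,3.6,-4.8,6.7,0.0,-1.3
0.048,28.1,19.3,19.5,4.2,3.4,34.4,6.0,-5.4,18.0,0.0,-3.6
0.096,59.5,36.8,39.5,16.2,6.5,61.8,13.8,-9.6,36.0,2.3,-7.4
0.194,100.4,60.4,66.7,27.5,11.4,97.3,23.4,-14.0,61.5,6.2,-11.9
0.387,149.8,88.6,101.2,43.2,14.9,136.7,34.5,-20.5,89.8,9.0,-15.2
0.580,180.4,104.7,122.3,52.0,17.2,159.9,41.5,-22.8,109.0,10.7,-17.7
1.060,219.2,112.1,145.3,53.7,13.7,167.2,42.1,-38.5,133.2,13.4,-15.7
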