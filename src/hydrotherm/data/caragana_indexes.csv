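no,type,species,n,wi_min,wi_max,wi_opt_lo,wi_opt_hi,wi_mean,wi_sd,ci_min,ci_max,ci_mean,ci_sd,hi_min,hi_max,hi_mean,hi_sd
1,5,C. acanthophylla,50,72.1,113.6,76.9,97.7,87.3,8.8,-106.6,-40.0,-58.7,9.1,0.9,12.2,6.3,3.1
2,5,C. arborescens,157,36.3,118.9,66.2,108.1,87.1,17.8,-143.1,-2.7,-48.8,30.2,2.0,12.0,6.2,2.0
3,5,C. aurantiaca,22,27.2,114.5,64.7,113.2,88.9,20.6,-78.9,-32.3,-47.8,10.9,0.6,17.4,3.8,4.4
4,5,C. boisii,7,76.3,117.8,78.4,119.8,99.1,17.6,-40.3,-3.4,-16.8,14.1,2.0,8.1,5.9,2.2
5,5,C. bongardiana,8,77.2,91.4,77.4,87.6,82.5,4.4,-70.1,-57.9,-63.2,4.2,2.1,11.3,5.4,3.6
6,4,C. brachypoda,48,60.3,92.4,67.8,92.6,80.2,10.5,-92.2,-26.1,-45.8,16.3,1.6,9.8,3.3,1.8
7,1,C. brevifolia,104,17.0,84.9,29.6,59.3,44.5,12.6,-80.4,-12.8,-45.5,12.5,3.9,44.5,14.1,9.0
8,4,C. camilloi-schneideri,10,75.9,97.0,77.4,97.4,87.4,8.5,-77.0,-49.5,-58.9,10.5,1.5,3.7,2.5,0.9
9,1,C. chinghaiensis,32,16.9,42.7,17.4,30.0,23.7,5.4,-87.1,-37.4,-67.1,12.1,9.5,52.0,29.1,12.0
10,4,C. dasyphylla,12,87.6,111.4,93.8,109.3,101.5,6.6,-65.6,-23.5,-33.4,10.8,0.4,6.5,1.9,1.6
11,5,C. davazamcii,5,72.9,89.9,74.1,90.9,82.5,7.1,-40.6,-29.4,-34.9,4.8,2.3,6.1,4.6,1.6
12,1,C. densa,35,18.9,101.5,28.8,81.1,55.0,22.2,-109.9,-13.3,-44.1,18.5,0.4,44.8,12.9,9.9
13,1,C. erinacea,46,15.7,83.6,13.2,53.8,33.5,17.3,-81.0,-8.4,-50.0,15.6,2.6,45.6,21.8,10.6
14,3,C. jubata,104,15.8,116.3,28.4,102.5,65.5,31.5,-80.4,-11.2,-43.8,14.0,0.7,44.5,10.7,9.8
15,1,C. junatovii,10,20.5,26.9,21.1,27.1,24.1,2.6,-70.7,-39.5,-55.5,11.7,17.6,29.2,22.6,4.5
16,5,C. kansuensis,56,64.5,110.1,70.2,93.0,81.6,9.7,-48.3,-14.3,-31.5,6.2,2.0,8.0,4.9,1.5
17,4,C. kirghisorum,6,90.4,96.9,91.6,97.4,94.5,2.5,-59.5,-50.0,-53.2,4.2,1.5,3.5,2.2,0.8
18,5,C. korshinskii,115,33.1,119.4,60.6,96.8,78.7,15.4,-91.4,-3.3,-44.1,17.9,0.8,14.9,4.8,2.5
19,5,C. leucophloea,112,48.5,126.8,69.0,100.2,84.6,13.3,-94.2,-23.5,-55.0,13.9,0.1,14.2,3.7,2.9
20,5,C. leveillei,40,83.5,122.0,87.6,114.6,101.1,11.5,-43.4,-1.9,-20.5,10.4,4.1,9.3,5.6,1.0
21,2,C. licentiana,44,32.0,91.6,51.4,83.2,67.3,13.5,-57.1,-16.7,-35.0,7.6,1.5,22.7,7.1,4.4
22,5,C. liouana,81,43.7,113.6,67.3,93.6,80.4,11.2,-120.1,-5.0,-44.1,16.9,1.6,14.2,5.0,1.8
23,5,C. microphylla,103,32.0,115.2,59.0,100.5,79.8,17.6,-120.1,-6.2,-52.2,29.6,2.1,22.7,5.6,2.3
24,2,C. opulens,169,22.9,112.7,46.1,92.9,69.5,19.9,-73.2,-5.1,-38.6,13.4,1.7,36.2,7.3,5.0
25,5,C. pekinensis,56,89.9,122.0,102.3,115.3,108.8,5.5,-43.9,-12.0,-24.5,5.3,4.1,6.0,5.1,0.4
26,4,C. pleiophylla,18,84.6,106.2,91.1,106.0,98.5,6.3,-66.7,-26.5,-38.3,11.5,0.4,7.6,1.9,1.8
27,4,C. polourensis,46,92.8,114.1,98.1,115.0,106.6,7.1,-52.8,-20.9,-28.2,6.4,0.2,3.1,1.1,0.9
28,5,C. potaninii,6,82.6,97.8,81.6,96.3,89.0,6.3,-44.2,-19.6,-34.7,9.9,4.6,6.6,5.3,0.8
29,4,C. pruinosa,18,73.8,113.6,83.4,110.4,96.9,11.5,-79.2,-26.5,-42.3,17.0,0.2,5.8,1.9,1.3
30,4,C. pumila,43,74.1,122.7,74.4,101.9,88.2,11.7,-82.3,-33.2,-57.6,11.5,0.6,10.1,3.3,2.4
31,5,C. purdomii,72,81.5,121.5,81.9,103.8,92.8,9.3,-45.4,-2.0,-26.5,9.2,1.7,9.0,5.7,1.2
32,2,C. pygmaea,50,58.8,104.2,58.5,84.3,71.4,11.0,-92.3,-24.2,-63.6,19.4,2.3,9.3,4.3,1.6
33,5,C. rosea,150,43.9,123.2,82.1,114.9,98.5,13.9,-62.0,-0.9,-28.2,11.9,3.3,15.2,5.8,1.4
34,5,C. sinica,94,49.7,122.5,86.5,121.5,104.0,14.9,-50.1,-1.2,-17.9,13.0,4.1,10.6,6.5,1.8
35,5,C. soongorica,23,76.9,113.6,79.6,98.1,88.8,7.9,-94.6,-43.2,-64.1,11.2,1.4,9.9,4.9,2.7
36,2,C. stenophylla,166,28.7,99.4,59.9,90.0,75.0,12.8,-128.3,-23.9,-55.9,25.1,1.4,15.2,4.0,2.0
37,5,C. stipitata,50,83.5,121.9,97.5,116.1,106.8,7.9,-33.9,-3.4,-13.6,7.5,4.1,9.3,7.1,1.3
38,1,C. tangutica,31,23.1,83.0,40.6,78.1,59.3,15.9,-49.7,-15.5,-32.4,10.8,2.9,27.7,8.6,6.0
39,2,C. tibetica,62,24.1,92.4,43.4,94.5,69.0,21.7,-68.7,-26.5,-41.2,10.7,1.7,22.9,6.4,5.8
40,4,C. tragacanthoides,11,73.1,84.8,73.3,84.0,78.7,4.5,-76.7,-61.8,-66.5,4.2,1.9,2.8,2.4,0.3
41,4,C. turfanensis,17,87.6,111.4,94.1,107.8,100.9,5.8,-65.6,-23.5,-35.2,10.0,0.7,6.5,1.8,1.4
42,5,C. turkestanica,8,73.8,106.2,71.4,98.7,85.0,11.6,-100.7,-26.5,-63.3,21.0,1.3,11.1,5.0,3.8
43,1,C. versicolor,9,16.3,58.8,12.5,53.7,33.1,17.5,-79.8,-35.1,-58.8,18.4,7.6,43.2,24.7,15.6
44,5,C. zahlbruckneri,49,65.1,115.2,80.7,111.2,95.9,13.0,-66.4,-15.2,-34.7,11.7,4.3,7.5,5.5,0.8
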