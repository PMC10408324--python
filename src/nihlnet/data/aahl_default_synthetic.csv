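age,f1,f2,f3,f4,f6,f8
18,0.0,0.0,0.0,0.0,0.0,0.0
20,0.0,0.0,0.0,0.1,0.1,0.1
25,0.2,0.3,0.6,0.8,0.9,1.1
30,0.6,1.0,1.7,2.3,2.6,3.2
35,1.2,2.0,3.3,4.6,5.2,6.4
40,2.1,3.4,5.6,7.7,8.7,10.6
45,3.1,5.1,8.4,11.7,13.1,16.0
50,4.4,7.2,11.8,16.4,18.4,22.5
55,5.9,9.6,15.7,21.9,24.6,30.1
60,7.6,12.3,20.3,28.2,31.8,38.8
65,9.5,15.5,25.4,35.3,39.8,48.6
70,11.6,18.9,31.1,43.3,48.7,59.5
75,14.0,22.7,37.4,52.0,58.5,71.5
80,16.5,26.9,44.2,61.5,69.2,84.6
85,19.3,31.4,51.6,71.8,80.8,98.8
90,22.3,36.3,59.6,82.9,93.3,114.0
95,25.5,41.5,68.2,94.9,106.7,130.4
100,28.9,47.1,77.3,107.6,121.0,147.9
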