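eye,age,side,auc,ideal_threshold,critical_amplitude,illum_sd,tot_movt
1,30,r,0.954,4.5,18.0,1.4,63.3
2,30,l,0.986,7,16.0,1.3,73.5
3,26,r,0.853,8,13.9,2.1,40.3
4,26,l,0.894,6,12.0,2.2,74.3
5,23,r,0.949,4.5,13.1,0.8,41.4
6,23,l,0.966,4,12.0,0.7,32.7
7,29,l,0.964,3,12.4,0.5,32.0
8,29,r,0.938,5,15.8,1.0,44.7
9,48,l,0.898,4,10.7,0.9,22.4
10,81,l,0.918,2,7.1,2.0,50.0
11,25,r,0.922,5.5,19.8,0.8,51.7
12,73,r,0.964,2.5,11.6,1.4,39.7
13,78,l,0.979,5,22.7,1.4,26.9
14,40,l,0.984,3.5,9.4,0.6,30.2
15,67,r,0.952,10,26.8,2.5,41.0
16,69,r,0.978,4,9.1,1.7,82.8
17,65,r,0.939,6,15.0,2.1,115.3
18,65,l,0.960,5,23.6,2.9,181.2
19,59,r,0.950,6,11.0,1.5,82.8
20,59,l,0.940,8.5,25.0,3.0,45.2
21,25,l,0.916,6.5,16.4,2.0,66.2
22,70,l,0.883,9.5,16.3,3.5,71.9
23,65,r,0.976,4,15.3,0.8,26.4
24,72,r,0.987,8.5,22.3,3.4,117.6
25,72,l,0.962,6,13.5,1.5,77.0
26,48,r,0.909,4,16.7,1.0,55.6
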