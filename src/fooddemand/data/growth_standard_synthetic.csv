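age,sex,height_cm,median_bmi,bmi_sd
0,male,49.9,13.4,1.3
1,male,75.7,17.2,1.6
2,male,87.1,16.5,1.5
3,male,96.1,15.9,1.5
4,male,103.3,15.5,1.5
5,male,110.0,15.3,1.5
6,male,116.0,15.3,1.6
7,male,121.7,15.5,1.7
8,male,127.3,15.7,1.8
9,male,132.6,16.0,1.9
10,male,137.8,16.4,2.0
11,male,143.1,16.9,2.1
12,male,149.1,17.5,2.2
13,male,156.0,18.2,2.3
14,male,163.2,19.0,2.3
15,male,169.0,19.8,2.4
16,male,172.9,20.5,2.4
17,male,175.2,21.1,2.4
18,male,176.5,21.7,2.4
0,female,49.1,13.3,1.3
1,female,74.0,16.8,1.6
2,female,85.7,16.2,1.5
3,female,95.1,15.7,1.5
4,female,102.7,15.4,1.5
5,female,109.4,15.2,1.6
6,female,115.1,15.3,1.7
7,female,120.8,15.5,1.8
8,female,126.6,15.9,1.9
9,female,132.5,16.3,2.0
10,female,138.6,16.9,2.1
11,female,145.0,17.7,2.2
12,female,151.2,18.4,2.3
13,female,156.4,19.1,2.3
14,female,159.8,19.8,2.4
15,female,161.7,20.4,2.4
16,female,162.5,20.9,2.4
17,female,162.9,21.3,2.4
18,female,163.1,21.6,2.4
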