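channel,source,detector,hemisphere,distance_mm
1,1,1,left,20.9
2,1,2,left,24.7
3,2,1,left,28.5
4,2,2,left,31.3
5,2,3,left,34.1
6,3,2,left,36.9
7,3,3,left,39.7
8,3,4,left,42.6
9,4,3,left,46.3
10,4,4,left,52.0
11,5,5,right,20.9
12,5,6,right,24.7
13,6,5,right,28.5
14,6,6,right,31.3
15,6,7,right,34.1
16,7,6,right,36.9
17,7,7,right,39.7
18,7,8,right,42.6
19,8,7,right,46.3
20,8,8,right,52.0
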