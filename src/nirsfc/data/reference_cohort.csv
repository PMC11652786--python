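subject_id,gestational_age_wk,postnatal_age_h,sex,head_circumference_mm,total_scan_s,post_segmentation_s,remainder_pct
1,40,21.5,male,,543.32,252.84,47
2,38.71,26,female,,603.59,461.24,76
3,39.14,8.5,female,,485.82,475.69,98
4,38.71,40.5,female,360,900.86,566.43,63
5,40.14,18,female,335,517.87,347.90,67
6,40.86,12,male,355,723.91,423.59,59
7,38.14,9,female,350,716.44,191.69,27
12,40,7,female,355,390.46,311.43,80
13,40.43,21,male,380,680.26,531.92,78
14,40.86,10,male,355,378.27,338.85,90
15,36.43,7,male,350,497.61,172.82,35
16,39.71,46,female,335,577.63,159.94,28
18,40,21.5,female,355,441.19,411.99,93
19,38.43,22,male,340,617.55,326.57,53
24,40.14,13,male,370,493.88,390.66,79
25,40.57,15.5,male,350,484.93,364.71,75
27,39,24,male,350,387.91,328.73,85
31,36.14,20,female,345,460.95,154.83,34
33,38.86,32,male,315,622.17,373.65,60
35,36.86,32,female,345,435.59,231.31,53
36,41.14,20,male,345,609.19,520.72,85
37,39,11,male,365,569.28,214.79,38
38,38.71,22,male,380,481.89,415.92,86
39,39.71,19.25,female,350,616.76,454.75,74
40,38.29,19,male,310,613.81,409.73,67
44,40.71,21,female,340,695.50,315.65,45
45,38.14,5,male,340,616.66,151.78,25
47,39,29,female,350,618.92,573.60,93
48,38.86,33,female,330,552.86,357.73,65
49,39.71,19,male,340,722.63,213.91,30
50,39,24,male,320,662.86,588.64,89
51,38.43,54,male,360,604.96,381.71,63
52,39.86,23,male,345,599.95,381.62,64
53,37.57,26,female,340,603.59,385.16,64
54,36.43,33,male,330,593.46,351.63,59
56,39,22.5,male,370,597.88,177.73,30
57,,,male,376,601.52,375.42,62
58,37.43,30,male,340,620.20,445.61,72
59,39.86,21,male,340,611.94,573.60,94
60,41.29,31,female,345,636.72,579.40,91
61,38,48,female,320,619.91,403.83,65
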