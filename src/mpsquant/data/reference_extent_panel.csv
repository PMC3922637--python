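patient,exini_extent,exini_sd_pct,ect_extent,ect_sd_pct,qps_extent,qps_sd_pct,fourdm_extent,fourdm_sd_pct,physician_median,physician_min,physician_max
1,27,16,3,6,15,3,14,6,26,8,65
2,0,6,0,0,0,0,0,0,6,1,25
3,9,7,3,7,7,4,2,3,14,6,22
4,19,13,18,7,24,19,15,7,23,15,34
5,8,10,14,15,2,3,7,3,25,3,34
6,21,24,37,26,37,35,61,40,27,12,41
7,4,15,1,1,5,4,5,15,10,4,29
8,0,6,17,7,6,10,24,12,6,0,22
9,17,16,16,10,18,12,25,12,24,14,31
10,17,10,10,1,20,13,3,3,17,4,31
11,26,18,7,6,9,9,19,13,25,2,43
12,3,7,4,6,8,7,13,9,7,2,17
13,22,22,15,6,15,15,29,24,24,15,41
14,59,34,12,15,0,0,14,13,54,27,74
15,9,10,32,16,9,9,22,16,16,2,32
16,0,9,3,6,5,6,12,12,12,0,26
17,16,13,11,7,4,3,10,6,30,10,42
18,14,10,10,3,5,9,11,10,28,11,43
19,43,32,26,22,32,19,35,18,43,24,66
20,11,9,6,10,10,12,9,6,14,3,22
21,38,24,34,21,21,19,34,22,46,17,61
22,34,26,15,0,9,10,17,16,38,14,73
23,7,4,3,6,14,6,9,3,7,3,24
24,5,7,5,4,4,3,8,3,9,1,29
25,16,18,12,9,13,12,17,13,22,9,36
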