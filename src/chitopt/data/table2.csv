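run_id,x1,x2,x3,yield_pct,dd_pct,mm_kda
1,-1,-1,-1,7.36,62.0,69.83
2,-1,-1,1,9.63,75.5,26.39
3,-1,1,-1,8.41,52.0,66.43
4,-1,1,1,10.09,62.5,67.04
5,1,-1,-1,7.76,100,363.62
6,1,-1,1,8.79,88.5,663.81
7,1,1,-1,7.62,82.95,541.53
8,1,1,1,8.7,91.5,825.00
9,-1.68,0,0,11.57,27.5,34.10
10,1.68,0,0,9.56,92.0,612.14
11,0,-1.68,0,10,88.5,475.43
12,0,1.68,0,9.32,93.77,413.22
13,0,0,-1.68,11.22,63.33,155.52
14,0,0,1.68,11.5,96.95,170.50
15,0,0,0,8.88,96.27,819.99
16,0,0,0,9.43,86.65,804.33
17,0,0,0,10.94,88.25,669.64
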