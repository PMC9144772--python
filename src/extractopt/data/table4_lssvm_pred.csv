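group,predicted
1,12.0440
2,12.3464
3,12.1006
4,12.4031
5,12.3770
6,12.6092
7,11.8379
8,12.0701
9,12.3350
10,12.6180
11,11.8291
12,12.1121
13,12.0862
14,12.1429
15,12.3042
16,12.3609
17,11.9634
18,12.2814
19,12.1657
20,12.4837
21,12.4576
22,12.5146
23,11.9325
24,11.9895
25,12.2235
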