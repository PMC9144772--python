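run_id,extraction_time,extraction_temperature,liquid_solid_ratio,ethanol_concentration,PolyIII,DISS,Y
1,60,40,10,70,1.4456,15.5484,12.0227
2,120,40,10,70,1.5295,16.1695,12.5095
3,60,60,10,70,1.4981,15.9899,12.3670
4,120,60,10,70,1.5736,16.1695,12.5205
5,90,50,8,55,1.4016,15.9492,12.3123
6,90,50,12,55,1.5044,15.9561,12.3432
7,90,50,8,85,1.4409,14.9479,11.5711
8,90,50,12,85,1.5486,15.2625,11.8340
9,60,50,10,55,1.3442,15.2710,11.7893
10,120,50,10,55,1.4611,15.9812,12.3512
11,60,50,10,85,1.3649,14.7946,11.4372
12,120,50,10,85,1.5000,14.9916,11.6187
13,90,40,8,70,1.4956,15.9583,12.3426
14,90,60,8,70,1.5200,16.1822,12.5166
15,90,40,12,70,1.5716,16.3750,12.6741
16,90,60,12,70,1.6158,16.2980,12.6275
17,60,50,8,70,1.3782,15.9690,12.3213
18,120,50,8,70,1.3829,16.2697,12.5480
19,60,50,12,70,1.4019,16.2483,12.5367
20,120,50,12,70,1.5831,16.7280,12.9418
21,90,40,10,55,1.4724,15.3066,11.8481
22,90,60,10,55,1.5987,15.9826,12.3866
23,90,40,10,85,1.5282,15.2000,11.7821
24,90,60,10,85,1.5159,14.7230,11.4212
25,90,50,10,70,1.6715,16.6493,12.9048
26,90,50,10,70,1.7005,16.7102,12.9578
27,90,50,10,70,1.6571,16.9221,13.1058
28,90,50,10,70,1.6694,16.8204,13.0327
29,90,50,10,70,1.6842,16.8039,13.0240
30,90,50,10,70,1.7018,16.8183,13.0392
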