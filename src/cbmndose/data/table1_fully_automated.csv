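dose_gy,n_bn,mn0,mn1,mn2,mn3,mn4
0,16020,15706,295,17,2,0
0.1,18000,17676,314,10,0,0
0.25,18000,17602,382,13,1,2
0.5,18000,17440,531,28,0,1
0.75,18000,17371,610,17,2,0
1.0,18000,17167,802,29,2,0
2.0,18000,16256,1630,111,3,0
3.0,17572,14933,2400,220,18,1
4.0,18000,14295,3215,455,34,1
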