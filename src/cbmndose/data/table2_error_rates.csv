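dose_gy,fp_bn_pct,fp_mn_pct,fn_mn_pct
0,0.98,0.67,1.12
0.1,0.72,0.73,1.02
0.25,0.80,0.72,1.33
0.5,1.16,1.02,1.77
0.75,1.09,0.76,1.68
1.0,1.02,1.04,2.04
2.0,0.87,1.36,4.43
3.0,1.38,1.50,7.37
4.0,2.20,1.46,10.78
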