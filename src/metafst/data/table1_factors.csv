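population_id,sample_size,fst_mean,fst_mode,hpdi_low,hpdi_high,age,size,s_t,s_s
1,24,0.183,0.174,0.128,0.248,21,22.038,2.15,44.543
2,12,0.2,0.188,0.111,0.302,3,1.246,0.143,1.246
3,7,0.108,0.096,0.041,0.186,3,4.485,0.51,9.304
4,5,0.177,0.147,0.0719,0.296,1,4.82,0.228,9.675
5,19,0.064,0.058,0.0298,0.1,21,13.477,6.192,54.116
6,50,0.046,0.043,0.0272,0.0665,21,9.023,4.37,18.625
7,22,0.056,0.051,0.0247,0.0886,18,5.956,5.308,23.917
8,24,0.048,0.045,0.0244,0.0744,21,10.309,5.218,21.658
9,39,0.041,0.039,0.0242,0.06,20,9.389,6.54,38.816
10,21,0.044,0.039,0.0197,0.0718,12,3.774,3.924,15.602
11,18,0.043,0.038,0.0199,0.0715,21,8.873,6.098,27.936
12,47,0.048,0.045,0.028,0.0713,18,1.733,5.362,7.004
13,8,0.071,0.054,0.014,0.142,21,7.827,6.256,31.624
14,20,0.064,0.059,0.0287,0.105,17,4.16,3.808,9.361
15,44,0.024,0.022,0.011,0.0376,10,6.521,1.663,8.719
16,11,0.156,0.139,0.0743,0.248,21,5.255,4.213,13.407
17,8,0.099,0.088,0.037,0.165,12,2.051,2.627,6.986
18,19,0.139,0.129,0.0784,0.209,4,3.84,0.876,13.077
19,10,0.179,0.166,0.0888,0.275,3,1.503,0.474,3.963
20,16,0.106,0.098,0.0533,0.163,1,1.392,0.139,3.147
21,10,0.166,0.15,0.0809,0.269,1,1.507,0.055,1.543
22,6,0.155,0.137,0.0669,0.252,12,5.771,1.175,11.573
23,36,0.11,0.106,0.0724,0.151,11,1.807,1.077,3.622
24,27,0.156,0.148,0.0962,0.223,3,2.345,0.19,2.408
25,8,0.218,0.205,0.119,0.334,1,1.486,0.066,1.506
26,21,0.116,0.107,0.0619,0.173,20,4.22,1.343,5.159
27,8,0.124,0.111,0.0572,0.2,21,7.679,2.696,15.767
28,4,0.075,0.066,0.0205,0.139,21,17.038,2.358,21.839
29,15,0.124,0.113,0.0649,0.188,21,19.11,2.283,21.082
30,44,0.113,0.107,0.0718,0.161,21,45.22,2.335,51.538
31,24,0.143,0.133,0.0885,0.209,4,1.535,0.614,3.454
32,29,0.136,0.129,0.0818,0.193,21,26.265,2.568,39.887
33,44,0.104,0.101,0.0677,0.143,1,1.161,0.128,2.166
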