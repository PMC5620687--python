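datum,agent,rate,stratum,mortality_type
1,tflavoorbitalis,0.106,unspecified,apparent
2,tflavoorbitalis,0.141,unspecified,apparent
3,tflavoorbitalis,0.303,unspecified,apparent
4,tflavoorbitalis,0.122,unspecified,apparent
5,tflavoorbitalis,0.489,unspecified,apparent
6,tflavoorbitalis,0.510,unspecified,apparent
7,tflavoorbitalis,0.243,unspecified,apparent
8,tflavoorbitalis,0.585,unspecified,apparent
9,tflavoorbitalis,0.338,unspecified,apparent
10,tflavoorbitalis,0.222,unspecified,apparent
11,tflavoorbitalis,0.411,unspecified,apparent
12,tflavoorbitalis,0.508,unspecified,apparent
13,tflavoorbitalis,0.295,unspecified,apparent
14,tflavoorbitalis,0.373,unspecified,apparent
15,tflavoorbitalis,0.174,unspecified,apparent
16,tflavoorbitalis,0.538,unspecified,apparent
17,tflavoorbitalis,0.333,unspecified,apparent
18,tflavoorbitalis,0.146,unspecified,apparent
19,tflavoorbitalis,0.430,unspecified,apparent
20,tflavoorbitalis,0.600,unspecified,apparent
21,tflavoorbitalis,0.123,unspecified,apparent
22,tflavoorbitalis,0.103,unspecified,apparent
23,tflavoorbitalis,0.152,unspecified,apparent
24,tflavoorbitalis,0.144,unspecified,apparent
25,tflavoorbitalis,0.193,unspecified,apparent
1,mlaphygmae,0.070,unspecified,apparent
2,mlaphygmae,0.001,unspecified,apparent
3,mlaphygmae,0.059,unspecified,apparent
4,mlaphygmae,0.001,unspecified,apparent
5,mlaphygmae,0.001,unspecified,apparent
6,mlaphygmae,0.001,unspecified,apparent
7,mlaphygmae,0.001,unspecified,apparent
8,mlaphygmae,0.001,unspecified,apparent
9,mlaphygmae,0.001,unspecified,apparent
10,mlaphygmae,0.001,unspecified,apparent
11,mlaphygmae,0.001,unspecified,apparent
12,mlaphygmae,0.001,unspecified,apparent
13,mlaphygmae,0.030,unspecified,apparent
14,mlaphygmae,0.001,unspecified,apparent
15,mlaphygmae,0.001,unspecified,apparent
16,mlaphygmae,0.001,unspecified,apparent
17,mlaphygmae,0.001,unspecified,apparent
18,mlaphygmae,0.001,unspecified,apparent
19,mlaphygmae,0.001,unspecified,apparent
20,mlaphygmae,0.001,unspecified,apparent
21,mlaphygmae,0.001,unspecified,apparent
22,mlaphygmae,0.014,unspecified,apparent
23,mlaphygmae,0.001,unspecified,apparent
24,mlaphygmae,0.001,unspecified,apparent
25,mlaphygmae,0.001,unspecified,apparent
1,cmarginiventris,0.088,unspecified,apparent
2,cmarginiventris,0.001,unspecified,apparent
3,cmarginiventris,0.176,unspecified,apparent
4,cmarginiventris,0.001,unspecified,apparent
5,cmarginiventris,0.083,unspecified,apparent
6,cmarginiventris,0.001,unspecified,apparent
7,cmarginiventris,0.001,unspecified,apparent
8,cmarginiventris,0.001,unspecified,apparent
9,cmarginiventris,0.001,unspecified,apparent
10,cmarginiventris,0.001,unspecified,apparent
11,cmarginiventris,0.001,unspecified,apparent
12,cmarginiventris,0.001,unspecified,apparent
13,cmarginiventris,0.091,unspecified,apparent
14,cmarginiventris,0.001,unspecified,apparent
15,cmarginiventris,0.071,unspecified,apparent
16,cmarginiventris,0.001,unspecified,apparent
17,cmarginiventris,0.001,unspecified,apparent
18,cmarginiventris,0.001,unspecified,apparent
19,cmarginiventris,0.001,unspecified,apparent
20,cmarginiventris,0.026,unspecified,apparent
21,cmarginiventris,0.001,unspecified,apparent
22,cmarginiventris,0.014,unspecified,apparent
23,cmarginiventris,0.001,unspecified,apparent
24,cmarginiventris,0.266,unspecified,apparent
25,cmarginiventris,0.302,unspecified,apparent
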