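datum,agent,rate,stratum,mortality_type
1,tflavoorbitalis,0.006,unspecified,marginal
2,tflavoorbitalis,0.040,unspecified,marginal
3,tflavoorbitalis,0.015,unspecified,marginal
4,tflavoorbitalis,0.001,unspecified,marginal
5,tflavoorbitalis,0.001,unspecified,marginal
6,tflavoorbitalis,0.053,unspecified,marginal
7,tflavoorbitalis,0.001,unspecified,marginal
8,tflavoorbitalis,0.001,unspecified,marginal
9,tflavoorbitalis,0.001,unspecified,marginal
10,tflavoorbitalis,0.128,unspecified,marginal
11,tflavoorbitalis,0.037,unspecified,marginal
12,tflavoorbitalis,0.035,unspecified,marginal
13,tflavoorbitalis,0.080,unspecified,marginal
14,tflavoorbitalis,0.009,unspecified,marginal
15,tflavoorbitalis,0.001,unspecified,marginal
16,tflavoorbitalis,0.017,unspecified,marginal
17,tflavoorbitalis,0.141,unspecified,marginal
18,tflavoorbitalis,0.031,unspecified,marginal
1,mlaphygmae,0.006,unspecified,marginal
2,mlaphygmae,0.000,unspecified,marginal
3,mlaphygmae,0.000,unspecified,marginal
4,mlaphygmae,0.000,unspecified,marginal
5,mlaphygmae,0.000,unspecified,marginal
6,mlaphygmae,0.000,unspecified,marginal
7,mlaphygmae,0.000,unspecified,marginal
8,mlaphygmae,0.000,unspecified,marginal
9,mlaphygmae,0.000,unspecified,marginal
10,mlaphygmae,0.000,unspecified,marginal
11,mlaphygmae,0.000,unspecified,marginal
12,mlaphygmae,0.000,unspecified,marginal
13,mlaphygmae,0.000,unspecified,marginal
14,mlaphygmae,0.000,unspecified,marginal
15,mlaphygmae,0.000,unspecified,marginal
16,mlaphygmae,0.000,unspecified,marginal
17,mlaphygmae,0.000,unspecified,marginal
18,mlaphygmae,0.000,unspecified,marginal
1,cmarginiventris,0.000,unspecified,marginal
2,cmarginiventris,0.000,unspecified,marginal
3,cmarginiventris,0.000,unspecified,marginal
4,cmarginiventris,0.000,unspecified,marginal
5,cmarginiventris,0.017,unspecified,marginal
6,cmarginiventris,0.000,unspecified,marginal
7,cmarginiventris,0.000,unspecified,marginal
8,cmarginiventris,0.000,unspecified,marginal
9,cmarginiventris,0.000,unspecified,marginal
10,cmarginiventris,0.000,unspecified,marginal
11,cmarginiventris,0.000,unspecified,marginal
12,cmarginiventris,0.000,unspecified,marginal
13,cmarginiventris,0.000,unspecified,marginal
14,cmarginiventris,0.000,unspecified,marginal
15,cmarginiventris,0.000,unspecified,marginal
16,cmarginiventris,0.000,unspecified,marginal
17,cmarginiventris,0.000,unspecified,marginal
18,cmarginiventris,0.000,unspecified,marginal
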