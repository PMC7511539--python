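pt,group,sex,age,competitiveness,eft,m_train,ipaq,vo2peak,wmax,gxt_hrmax,gxt_rermax,gxt_rpemax,iet_hrmax,iet_rpemax
1,Low,F,23,6,0,24,3106.5,47.2,230,182,1.12,17,100,7
2,Low,M,23,7,22,26,462,38.3,160,180,1.16,18,94,7
3,Low,F,21,5,16,12,1108.5,29.3,110,183,1.2,18,107,10
4,Low,F,25,3,18,1,537,28.9,110,165,1.04,15,107,8
5,Low,M,20,7,12,0.75,758,43.3,190,203,1.12,17,119,9
6,Low,F,24,2,6,24,132,26.9,110,140,1.38,18,122,10
7,Low,M,21,6,1,2,3804,31.9,220,181,1.15,19,105,14
8,Low,F,18,2,2,0,1320,24.8,80,146,1.19,16,105,10
9,Low,M,18,7,0,0,660,35.9,160,192,1.19,20,130,10
10,Low,F,20,5,0,12,702,23.5,80,186,1.19,18,132,9
11,Low,M,22,6,12,24,6984,44,220,193,1.17,16,97,9
12,Low,F,23,1,6,1.5,1986,22.9,80,177,1.13,17,113,11
13,High,M,24,5,0,58,798,41.6,220,196,1.17,19,183,16
14,High,F,30,7,3,12,3999,25.1,110,164,1.12,16,156,15
15,High,M,24,6,17,0.5,1155,24.6,100,171,1.27,15,179,18
16,High,F,21,5,3,36,660,19.8,80,189,1.18,17,193,18
17,High,F,23,4,13,0,66,27.8,110,173,1.18,18,173,19
18,High,F,19,6,7,5,693,27.6,110,178,1.14,17,181,17
19,High,F,24,6,5,2,4158,38.5,170,178,1.14,18,174,18
20,High,F,23,7,12,12,3132,28.7,140,189,1.21,19,181,20
21,High,F,20,7,0,18,330,25.1,110,182,1.11,17,172,16
22,High,F,18,3,0,0.75,912,22.4,110,182,1.13,20,177,13
23,High,M,18,7,4,1,1158,46,220,174,1.09,17,176,15
24,High,M,23,4,4,10,758,32.6,160,195,1.17,17,202,19
25,High,M,22,5,8,5,4158,36.9,190,179,1.25,19,170,16
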