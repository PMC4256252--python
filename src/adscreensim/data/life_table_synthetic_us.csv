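# Synthetic life table: Gompertz approximation to the US (CDC-style) period life table.
# q = annual probability of death at the given age, by sex. Terminal age 120 has q=1.
age,sex,q
50,male,0.005624
51,male,0.006108
52,male,0.006634
53,male,0.007206
54,male,0.007826
55,male,0.008500
56,male,0.009232
57,male,0.010027
58,male,0.010890
59,male,0.011828
60,male,0.012846
61,male,0.013953
62,male,0.015154
63,male,0.016459
64,male,0.017876
65,male,0.019415
66,male,0.021087
67,male,0.022903
68,male,0.024875
69,male,0.027017
70,male,0.029343
71,male,0.031870
72,male,0.034614
73,male,0.037595
74,male,0.040832
75,male,0.044348
76,male,0.048167
77,male,0.052314
78,male,0.056819
79,male,0.061711
80,male,0.067025
81,male,0.072796
82,male,0.079065
83,male,0.085873
84,male,0.093267
85,male,0.101298
86,male,0.110020
87,male,0.119494
88,male,0.129783
89,male,0.140959
90,male,0.153096
91,male,0.166279
92,male,0.180597
93,male,0.196147
94,male,0.213037
95,male,0.231381
96,male,0.251305
97,male,0.272944
98,male,0.296446
99,male,0.321973
100,male,0.349697
101,male,0.379808
102,male,0.412512
103,male,0.448033
104,male,0.486612
105,male,0.528512
106,male,0.574021
107,male,0.623449
108,male,0.677132
109,male,0.700000
110,male,0.700000
111,male,0.700000
112,male,0.700000
113,male,0.700000
114,male,0.700000
115,male,0.700000
116,male,0.700000
117,male,0.700000
118,male,0.700000
119,male,0.700000
120,male,1.000000
50,female,0.003234
51,female,0.003543
52,female,0.003880
53,female,0.004251
54,female,0.004656
55,female,0.005100
56,female,0.005586
57,female,0.006119
58,female,0.006703
59,female,0.007342
60,female,0.008043
61,female,0.008810
62,female,0.009650
63,female,0.010570
64,female,0.011578
65,female,0.012683
66,female,0.013892
67,female,0.015217
68,female,0.016669
69,female,0.018259
70,female,0.020000
71,female,0.021908
72,female,0.023997
73,female,0.026286
74,female,0.028793
75,female,0.031539
76,female,0.034548
77,female,0.037843
78,female,0.041452
79,female,0.045406
80,female,0.049737
81,female,0.054480
82,female,0.059677
83,female,0.065369
84,female,0.071603
85,female,0.078433
86,female,0.085913
87,female,0.094108
88,female,0.103084
89,female,0.112916
90,female,0.123685
91,female,0.135482
92,female,0.148404
93,female,0.162559
94,female,0.178064
95,female,0.195047
96,female,0.213650
97,female,0.234028
98,female,0.256349
99,female,0.280799
100,female,0.307582
101,female,0.336918
102,female,0.369053
103,female,0.404253
104,female,0.442810
105,female,0.485044
106,female,0.531307
107,female,0.581983
108,female,0.637491
109,female,0.698294
110,female,0.700000
111,female,0.700000
112,female,0.700000
113,female,0.700000
114,female,0.700000
115,female,0.700000
116,female,0.700000
117,female,0.700000
118,female,0.700000
119,female,0.700000
120,female,1.000000
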