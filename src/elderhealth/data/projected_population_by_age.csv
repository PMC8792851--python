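age_group,year,state,population_10k
60-64,2015,1,1184
60-64,2015,2,2489
60-64,2015,3,2836
60-64,2015,4,1334
60-64,2025,1,1464
60-64,2025,2,3136
60-64,2025,3,3595
60-64,2025,4,1704
60-64,2035,1,1628
60-64,2035,2,3489
60-64,2035,3,3999
60-64,2035,4,1896
65-69,2015,1,686
65-69,2015,2,1853
65-69,2015,3,1968
65-69,2015,4,984
65-69,2025,1,838
65-69,2025,2,2332
65-69,2025,3,2540
65-69,2025,4,1267
65-69,2035,1,1275
65-69,2035,2,3707
65-69,2035,3,4076
65-69,2035,4,1994
70-74,2015,1,477
70-74,2015,2,1070
70-74,2015,3,1318
70-74,2015,4,762
70-74,2025,1,771
70-74,2025,2,1927
70-74,2025,3,2370
70-74,2025,4,1394
70-74,2035,1,1032
70-74,2035,2,2503
70-74,2035,3,3279
70-74,2035,4,1811
75-79,2015,1,361
75-79,2015,2,822
75-79,2015,3,943
75-79,2015,4,506
75-79,2025,1,542
75-79,2025,2,1144
75-79,2025,3,1529
75-79,2025,4,771
75-79,2035,1,711
75-79,2035,2,1434
75-79,2035,3,1977
75-79,2035,4,1112
80+,2015,1,446
80+,2015,2,745
80+,2015,3,863
80+,2015,4,465
80+,2025,1,615
80+,2025,2,988
80+,2025,3,1141
80+,2025,4,596
80+,2035,1,1102
80+,2035,2,1791
80+,2035,3,2024
80+,2035,4,1067
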