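# label: 70-74
# period_years: 2
state,1,2,3,4,5
1,0.3124,0.3048,0.2015,0.1302,0.0511
2,0.1328,0.3346,0.3706,0.1209,0.0411
3,0.0917,0.2711,0.3815,0.2093,0.0464
4,0.0561,0.1931,0.3207,0.3412,0.0889
5,0,0,0,0,1
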