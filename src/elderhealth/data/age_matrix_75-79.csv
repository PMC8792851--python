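# label: 75-79
# period_years: 2
state,1,2,3,4,5
1,0.2683,0.3293,0.2317,0.0976,0.0731
2,0.1409,0.3264,0.3149,0.1340,0.0838
3,0.1011,0.2523,0.3685,0.1721,0.1060
4,0.036,0.2432,0.3333,0.3063,0.0812
5,0,0,0,0,1
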