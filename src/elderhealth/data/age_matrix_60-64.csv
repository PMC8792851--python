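# label: 60-64
# period_years: 2
state,1,2,3,4,5
1,0.3552,0.3271,0.2526,0.0421,0.0230
2,0.1552,0.3841,0.3610,0.0909,0.0088
3,0.1002,0.3155,0.3662,0.1976,0.0205
4,0.04,0.1507,0.4141,0.3603,0.0349
5,0,0,0,0,1
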