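# label: 80+
# period_years: 2
state,1,2,3,4,5
1,0.2947,0.2549,0.3197,0.0717,0.0588
2,0.1405,0.3841,0.2222,0.1316,0.1218
3,0.1419,0.1768,0.3416,0.1707,0.1689
4,0.0752,0.1821,0.2875,0.237,0.2183
5,0,0,0,0,1
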