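# label: 65-69
# period_years: 2
state,1,2,3,4,5
1,0.2757,0.3964,0.2073,0.0657,0.0649
2,0.1323,0.3853,0.3667,0.0971,0.0186
3,0.0883,0.3212,0.3681,0.2001,0.0223
4,0.0546,0.1921,0.3751,0.3334,0.0448
5,0,0,0,0,1
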