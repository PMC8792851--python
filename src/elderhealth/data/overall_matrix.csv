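# label: overall
# period_years: 2
state,1,2,3,4,5
1,0.3211,0.3561,0.2342,0.0544,0.0342
2,0.1459,0.3707,0.3492,0.1054,0.0288
3,0.1007,0.2933,0.3674,0.1973,0.0413
4,0.0441,0.1826,0.3745,0.3352,0.0636
5,0,0,0,0,1
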