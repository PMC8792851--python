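state,percent_2011,percent_2013
1,12.15,12.96
2,29.82,30.22
3,38.49,34.86
4,19.54,17.92
5,,4.05
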