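state,family_annual,individual_monthly
1,3171.16,177.81
2,3851.09,175.73
3,4579.76,315.99
4,7200.96,647.86
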