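age_group,state,family_annual,individual_monthly
60-64,1,3010.94,92.21
60-64,2,4247.63,162.76
60-64,3,4673.69,308.49
60-64,4,8801.67,738.63
65-69,1,4451.52,125.01
65-69,2,3728.46,152.19
65-69,3,4740.35,367.76
65-69,4,6600.16,636.52
70-74,1,3232.45,88.63
70-74,2,3419.31,153.79
70-74,3,4925.58,269.03
70-74,4,6848.63,618.45
75-79,1,1662.97,84.36
75-79,2,3763.87,241.65
75-79,3,4104.32,354.14
75-79,4,7135.99,729.68
80+,1,2125.19,355.69
80+,2,3720.39,263.43
80+,3,3855.74,449.04
80+,4,5144.09,589.11
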