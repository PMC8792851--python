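state,population
1,59380000
2,133780000
3,149830000
4,75090000
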