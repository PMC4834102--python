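row,n,denominator,percent,ci_low,ci_high
overall_pip,57,190,30,23.5,36.5
1_pip,52,190,27.4,21,33.7
2_pip,5,190,2.6,0.4,4.9
3plus_pip,0,190,0,0,0
duplication,5,190,2.6,0.4,4.9
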