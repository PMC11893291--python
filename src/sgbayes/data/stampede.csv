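subgroup,label,hr,ci_lo,ci_hi
B,non-metastatic,0.75,0.48,1.18
C,metastatic,0.61,0.49,0.75
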