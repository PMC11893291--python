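subgroup,label,hr,ci_lo,ci_hi
B,bone metastases,0.54,0.34,0.84
C,no bone metastases,0.71,0.55,0.91
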