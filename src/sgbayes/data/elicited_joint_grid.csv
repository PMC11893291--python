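hr_C,0.5,0.6,0.7,0.8,0.9,1.0
0.5,0.0030,0.0025,0.0020,0.0015,0.0005,0.0005
0.6,0.0090,0.0315,0.0225,0.0135,0.0090,0.0045
0.7,0.0150,0.0300,0.1050,0.0900,0.0450,0.0150
0.8,0.0000,0.0175,0.0525,0.1400,0.1050,0.0350
0.9,0.0000,0.0000,0.0100,0.0400,0.0900,0.0600
1.0,0.0000,0.0000,0.0005,0.0020,0.0050,0.0425
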