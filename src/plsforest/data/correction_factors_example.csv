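zone,corner_type,era,f_design,f_size
Z1,section,E1,1.00,0.85
Z1,quarter-section,E1,1.00,0.85
Z1,section,E2,0.80,0.85
Z1,quarter-section,E2,0.80,0.85
Z2,section,E1,1.10,0.90
Z2,quarter-section,E1,1.05,0.90
Z2,section,E2,0.90,0.90
Z2,quarter-section,E2,0.85,0.90
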