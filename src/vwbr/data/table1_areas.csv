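volume_mL,area_cm2,specific_area_per_m
60.0,15.6,26.1
85.0,16.1,18.9
100,16.4,16.4
105,16.5,15.7
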