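species,body_weight_kg,brain_weight_g,mlp_years
mouse,0.02,0.36,3
rat,0.25,1.8,4.4
monkey,3.5,63,18
human,70,1400,93.4
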