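name: E
vessel_density_mm2: 80.0
vessel_removal_prob: 0.02
vessel_pattern: random
necrosis_exponent_atp: 1.0
necrosis_exponent_oxygen: 1.0
seed: null
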