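c: 25.0
psi0: 2.0833333333333335
epsilon: 0.12
velocity_set: two_point
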