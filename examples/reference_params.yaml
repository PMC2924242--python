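D_rho: 300.0
D_S: 800.0
D_N: 800.0
alpha: 0.0243
beta: 0.002
gamma: 0.0004
u_S: 3.0
u_N: 2.4
delta: 0.1
M: 100000.0
L: 10000.0
N0: 1000.0
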