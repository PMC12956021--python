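# Two-state switching model at the study parameterization: equilibrium
# resistant fraction from the survival balance f*e^(gamma*T) = 0.9 with
# T = 24 h and suspension doubling time 100 h (f ~ 0.76), resistant-state
# memory 10.5 generations, 20 expansion generations, 250,000 cells plated,
# 60 clones.
kind: two_state
version: 1
description: two-state switching null model, study protocol
S_mean: 0.9
T: 24.0
T_d_susp: 100.0
T_d_2D: 38.0
M: 10.5
G: 20
N0: 250000
n_clones: 60
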