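constant,experimental,simulation,adjusted_simulation
k,1.68,3.85,1.82
alpha,0.551,0.532,0.532
beta,0.333,0.333,0.333
gamma,1.18,0.947,0.947
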