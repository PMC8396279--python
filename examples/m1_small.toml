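# Scaled-down hairy-particle state point: model M1, sigma_c = 4 sigma,
# f = 20 chains of M = 10 segments, fluid density rho0 = 0.01.
variant = "M1"
f = 20
M = 10
geometry = "sphere"
sigma_c = 4.0
eps_Ps = 1.5
L = 30.0
rho0 = [0.01]
equilibration_steps = 100000
production_steps = 100000
sample_interval = 200
seeds = [1, 2, 3]
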