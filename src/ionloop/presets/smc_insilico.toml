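# Sliding-mode controller preset for the in silico experiment.
kappa1 = 0.1
kappa2 = 0.05
rho1 = 0.01
rho2 = 0.07
A_max = 1.5
T = 1.0
mu = -1
u_init = 0.0
n = 1200
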