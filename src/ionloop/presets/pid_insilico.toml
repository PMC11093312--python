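# Hard-clipped PID baseline for the in silico comparison.
#
# Gains are artifact-chosen (none were published) and deliberately place
# the loop near the saturation bound so the clip engages on transients:
# the comparison with the SMC is structural (bound violation of the raw
# command vs. built-in compliance), not a numeric benchmark.
kp = 0.3
ki = 0.02
kd = 0.05
A_max = 1.5
T = 1.0
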