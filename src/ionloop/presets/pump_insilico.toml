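# Simulated ion-pump plant preset, fluorescence-intensity scale.
#
# These are NOT experimentally fitted values (the fitted parameters of the
# underlying proton-pump dataset were never published); they are chosen so
# the plant behaves like the device the in silico experiment describes:
# a first-order response with ~17 s time constant whose output settles near
# 17.5 for a saturated voltage within A_max = 1.5 V, starting from an empty
# target and a well-stocked reservoir.  Region thresholds epsilon/zeta sit
# at 0.5 V, below the device's typical 0.5-2 V operating range.
D = 0.01
c1 = 1.0
c2 = 1.0
cc1 = 0.5
cc2 = 0.5
d1 = 50.0
d2 = 50.0
dd1 = 50.0
dd2 = 50.0
g = 0.05
epsilon = 0.5
zeta = 0.5
x1_init = 0.0
x2_init = 50.0
T = 1.0
substeps = 10
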