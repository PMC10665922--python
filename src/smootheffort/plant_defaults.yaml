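# Identified constants of the coupled human-exoskeleton forearm.
# Units: inertia, inertial_shift kg.m^2; damping N.m.s/rad;
# weight_moment kg.m; g0 m/s^2.
inertia: 0.35
inertial_shift: 0.0
damping: 0.05
weight_moment: 0.2934
g0: 9.81
# Gate of the inertial shift per (movement direction, acceleration phase).
# All-zero = ideal exoskeleton (shift never engaged); set entries to 1 to
# engage the identified shift for that direction/phase.
sigma_rule:
  "upward,acceleration": 0
  "upward,deceleration": 0
  "downward,acceleration": 0
  "downward,deceleration": 0
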