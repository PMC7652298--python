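# Analytic test model: two effective links a1 = a2 = 0.5 m, every other
# link parameter zero, so at q = 0 the end-effector sits at (1.0, 0, 0) and
# the whole chain can be verified by hand. Wide limits keep the model out
# of the feasibility checks' way.
name: planar-test
dh:
  - {a: 0.5, alpha: 0, d: 0.0}
  - {a: 0.5, alpha: 0, d: 0.0}
  - {a: 0.0, alpha: 0, d: 0.0}
  - {a: 0.0, alpha: 0, d: 0.0}
  - {a: 0.0, alpha: 0, d: 0.0}
  - {a: 0.0, alpha: 0, d: 0.0}
joint_limits_deg:
  - [-360, 360]
  - [-360, 360]
  - [-360, 360]
  - [-360, 360]
  - [-360, 360]
  - [-360, 360]
velocity_limits_deg_s: [180, 180, 180, 360, 360, 720]
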