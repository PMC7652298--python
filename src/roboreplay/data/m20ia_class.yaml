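# Approximate M20iA-class 6R industrial manipulator.
#
# The kinematic parameters below are an approximation of a ~1.8 m reach,
# 20 kg payload industrial arm assembled from vendor-published reach, stroke
# and speed figures; they are NOT factory calibration data. Joint speed
# limits follow the published axis ratings. Standard DH convention; angles
# in degrees, lengths in meters.
name: m20ia-class
dh:
  - {a: 0.150, alpha: -90, d: 0.525, theta_offset: 0}
  - {a: 0.790, alpha: 0,   d: 0.000, theta_offset: -90}
  - {a: 0.150, alpha: -90, d: 0.000, theta_offset: 0}
  - {a: 0.000, alpha: 90,  d: 0.860, theta_offset: 0}
  - {a: 0.000, alpha: -90, d: 0.000, theta_offset: 0}
  - {a: 0.000, alpha: 0,   d: 0.100, theta_offset: 0}
joint_limits_deg:
  - [-185, 185]
  - [-100, 160]
  - [-180, 260]
  - [-200, 200]
  - [-140, 140]
  - [-270, 270]
velocity_limits_deg_s: [195, 175, 180, 360, 360, 550]
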