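# Side-of-amputation sign normalization.
#
# A left-side prosthesis mirrors the device frame relative to a right-side
# fitting, so channels sensing mediolateral quantities change sign.  The set
# of affected channels is configuration: edit this file (or pass a custom map
# to load_sign_map) to match a particular device build.  Values must be +1
# (keep) or -1 (reverse when side == left).
channels:
  knee_angle: 1
  knee_velocity: 1
  knee_torque: 1
  ankle_angle: 1
  ankle_velocity: 1
  ankle_torque: 1
  axial_load: 1
  accel_x: 1
  accel_y: -1
  accel_z: 1
  gyro_x: -1
  gyro_y: 1
  gyro_z: -1
  thigh_angle: 1
  thigh_velocity: 1
  shank_angle: 1
  shank_velocity: 1
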