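classifier:
  classes:
    bract:
      area_rule:
      - 4500
      - keep_ge
      close_radius: 5
      dilate_radius: 3
      h_range:
      - 0.48
      - 0.6
      median_size: 5
      open_radius: 3
      s_range:
      - 0.15
      - 0.25
    corncob:
      area_rule: null
      close_radius: 5
      dilate_radius: 3
      h_range:
      - 0.8
      - 1.0
      median_size: 5
      open_radius: 3
      s_range:
      - 0.06
      - 0.7
    stone:
      area_rule:
      - 400
      - keep_lt
      close_radius: 5
      dilate_radius: 3
      h_range:
      - 0.55
      - 0.65
      median_size: 5
      open_radius: 3
      s_range:
      - 0.28
      - 1.0
  enhance: true
  priority:
  - stone
  - corncob
  - bract
  source: original
content:
  rho_w: 0.00731
  rho_z: 0.00105
msrcr:
  alpha: 125.0
  beta: 46.0
  clip_high: 99.0
  clip_low: 1.0
  epsilon: 1.0e-09
  scales:
  - 15.0
  - 80.0
  - 250.0
  weights:
  - 0.3333333333333333
  - 0.3333333333333333
  - 0.3333333333333333
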