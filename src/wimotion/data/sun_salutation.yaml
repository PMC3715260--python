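states:
- name: q0
  pose: 0
  theta_deg:
  - 180.0
  - 180.0
  - 180.0
  - 180.0
  - 180.0
  support_deg: 49.0
  core_deg: 19.6
- name: q1
  pose: 1
  theta_deg:
  - 20.0
  - 20.0
  - 170.0
  - 180.0
  - 180.0
  support_deg: 56.0
  core_deg: 22.400000000000002
- name: q2
  pose: 2
  theta_deg:
  - 160.0
  - 160.0
  - 90.0
  - 175.0
  - 175.0
  support_deg: 49.0
  core_deg: 19.6
- name: q3
  pose: 3
  theta_deg:
  - 170.0
  - 170.0
  - 95.0
  - 90.0
  - 90.0
  support_deg: 29.749999999999996
  core_deg: 11.899999999999999
- name: q4
  pose: 4
  theta_deg:
  - 120.0
  - 120.0
  - 130.0
  - 105.0
  - 105.0
  support_deg: 17.5
  core_deg: 7.0
- name: q5
  pose: 5
  theta_deg:
  - 40.0
  - 40.0
  - 60.0
  - 120.0
  - 120.0
  support_deg: 28.0
  core_deg: 11.200000000000001
motion_low_dps: 3.0
motion_high_dps: 12.0
closing_edge: true
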