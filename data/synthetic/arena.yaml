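cup_left_cm:
- 11.833333333333334
- 15.0
cup_radius_cm: 4.0
cup_right_cm:
- 59.166666666666664
- 15.0
depth_cm: 30.0
width_cm: 71.0
zone_margin_cm: 3.0
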