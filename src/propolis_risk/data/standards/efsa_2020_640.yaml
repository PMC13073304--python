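name: efsa_2020_640
description: European (EFSA) limits for trace elements in propolis.
limits:
  Cd: 0.1
  Pb: 1.0
  As: absent
daily_intake_bounds_mg:
  Mn: 3.0
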