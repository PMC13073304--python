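name: iram_inta_15935
description: Argentine standard limits for trace elements in propolis.
limits:
  Pb: 10.0
  As: 2.0
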