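name: nrag_1135
description: Cuban standard limits for trace elements in propolis.
limits:
  Pb: 2.0
  As: 1.0
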