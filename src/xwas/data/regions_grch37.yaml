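# Default X-chromosome region intervals (GRCh37/hg19 coordinates).
# These are packaged defaults, not an assertion about any particular data
# set: map positions from other genome builds need their own config.
# Intervals are half-open [start, end) in 1-based bp.
build: GRCh37
par1: [60001, 2699521]
par2: [154931044, 155260561]
xy_homologous:
  # Xq21.3 block homologous to Yp11; approximate envelope.
  - [88300000, 92000000]
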