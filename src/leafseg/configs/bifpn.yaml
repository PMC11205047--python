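# BiFPN-neck variant: the neck concatenations are replaced by fast
# normalised weighted-fusion nodes; the bottom-up output nodes include the
# same-level skip connection (backbone input, transition feature, and the
# resampled previous-level output).
backbone:
  - [-1, 1, Conv, [64, 3, 2]]       # 0  P1/2
  - [-1, 1, Conv, [128, 3, 2]]      # 1  P2/4
  - [-1, 3, C2f, [128, true]]       # 2
  - [-1, 1, Conv, [256, 3, 2]]      # 3  P3/8
  - [-1, 6, C2f, [256, true]]       # 4
  - [-1, 1, Conv, [512, 3, 2]]      # 5  P4/16
  - [-1, 6, C2f, [512, true]]       # 6
  - [-1, 1, Conv, [1024, 3, 2]]     # 7  P5/32
  - [-1, 3, C2f, [1024, true]]      # 8
  - [-1, 1, SPPF, [1024, 5]]        # 9
neck:
  - [-1, 1, Upsample, []]                    # 10  up(P5)
  - [[6, -1], 1, WeightedFusion, [512]]      # 11  P4 transition fuse
  - [-1, 3, C2f, [512, false]]               # 12  P4 td
  - [-1, 1, Upsample, []]                    # 13  up(P4 td)
  - [[4, -1], 1, WeightedFusion, [256]]      # 14  P3 transition fuse
  - [-1, 3, C2f, [256, false]]               # 15  P3 out
  - [-1, 1, Conv, [512, 3, 2]]               # 16  down(P3 out)
  - [[6, 12, -1], 1, WeightedFusion, [512]]  # 17  P4 out fuse (same-level skip)
  - [-1, 3, C2f, [512, false]]               # 18  P4 out
  - [-1, 1, Conv, [1024, 3, 2]]              # 19  down(P4 out)
  - [[9, -1], 1, WeightedFusion, [1024]]     # 20  P5 out fuse
  - [-1, 3, C2f, [1024, false]]              # 21  P5 out
head:
  - [[15, 18, 21], 1, Segment, []]           # 22
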