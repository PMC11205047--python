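# Ghost-backbone variant: the P4 downsampling convolution block is replaced
# by a Ghost module (dense primary 1x1 + cheap depthwise 5x5 ghosts).
# GhostConv args: [out, ratio, primary_kernel, cheap_kernel, stride]
backbone:
  - [-1, 1, Conv, [64, 3, 2]]           # 0  P1/2
  - [-1, 1, Conv, [128, 3, 2]]          # 1  P2/4
  - [-1, 3, C2f, [128, true]]           # 2
  - [-1, 1, Conv, [256, 3, 2]]          # 3  P3/8
  - [-1, 6, C2f, [256, true]]           # 4
  - [-1, 1, GhostConv, [512, 2, 1, 5, 2]]  # 5  P4/16 (Ghost substitution)
  - [-1, 6, C2f, [512, true]]           # 6
  - [-1, 1, Conv, [1024, 3, 2]]         # 7  P5/32
  - [-1, 3, C2f, [1024, true]]          # 8
  - [-1, 1, SPPF, [1024, 5]]            # 9
neck:
  - [-1, 1, Upsample, []]           # 10
  - [[-1, 6], 1, Concat, []]        # 11
  - [-1, 3, C2f, [512, false]]      # 12  P4 td
  - [-1, 1, Upsample, []]           # 13
  - [[-1, 4], 1, Concat, []]        # 14
  - [-1, 3, C2f, [256, false]]      # 15  P3 out
  - [-1, 1, Conv, [256, 3, 2]]      # 16
  - [[-1, 12], 1, Concat, []]       # 17
  - [-1, 3, C2f, [512, false]]      # 18  P4 out
  - [-1, 1, Conv, [512, 3, 2]]      # 19
  - [[-1, 9], 1, Concat, []]        # 20
  - [-1, 3, C2f, [1024, false]]     # 21  P5 out
head:
  - [[15, 18, 21], 1, Segment, []]  # 22
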