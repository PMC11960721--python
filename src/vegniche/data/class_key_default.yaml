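N:
  1:
  - 0.0
  - 1.5625
  2:
  - 1.25
  - 1.5625
  3:
  - 2.5
  - 1.5625
  4:
  - 3.75
  - 1.5625
  5:
  - 5.0
  - 1.5625
  6:
  - 6.25
  - 1.5625
  7:
  - 7.5
  - 1.5625
  8:
  - 8.75
  - 1.5625
  9:
  - 10.0
  - 1.5625
light:
  1:
  - 0.02
  - 0.015006249999999999
  2:
  - 0.1425
  - 0.015006249999999999
  3:
  - 0.265
  - 0.015006249999999999
  4:
  - 0.3875
  - 0.015006249999999999
  5:
  - 0.51
  - 0.015006249999999999
  6:
  - 0.6325000000000001
  - 0.015006249999999999
  7:
  - 0.755
  - 0.015006249999999999
  8:
  - 0.8775
  - 0.015006249999999999
  9:
  - 1.0
  - 0.015006249999999999
moisture:
  1:
  - 0.05
  - 0.012656249999999997
  2:
  - 0.16249999999999998
  - 0.012656249999999997
  3:
  - 0.27499999999999997
  - 0.012656249999999997
  4:
  - 0.38749999999999996
  - 0.012656249999999997
  5:
  - 0.49999999999999994
  - 0.012656249999999997
  6:
  - 0.6125
  - 0.012656249999999997
  7:
  - 0.725
  - 0.012656249999999997
  8:
  - 0.8374999999999999
  - 0.012656249999999997
  9:
  - 0.95
  - 0.012656249999999997
pH:
  1:
  - 3.0
  - 0.25
  2:
  - 3.5
  - 0.25
  3:
  - 4.0
  - 0.25
  4:
  - 4.5
  - 0.25
  5:
  - 5.0
  - 0.25
  6:
  - 5.5
  - 0.25
  7:
  - 6.0
  - 0.25
  8:
  - 6.5
  - 0.25
  9:
  - 7.0
  - 0.25
rooting_depth:
  1: 0.05
  2: 0.1
  3: 0.2
  4: 0.4
  5: 0.8
shading_height:
  1: 0.05
  2: 0.15
  3: 0.3
  4: 0.6
  5: 1.0
  6: 1.4
  7: 1.8
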