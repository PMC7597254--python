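canvas_shape:
- 513
- 911
rois:
  ROI1:
    name: forehead
    vertices_xy:
    - - 273.3
      - 55.917
    - - 637.6999999999999
      - 55.917
    - - 637.6999999999999
      - 110.295
    - - 273.3
      - 110.295
  ROI2:
    name: right_cheek
    vertices_xy:
    - - 229.572
      - 256.5
    - - 353.468
      - 256.5
    - - 353.468
      - 338.58000000000004
    - - 229.572
      - 338.58000000000004
  ROI3:
    name: nose
    vertices_xy:
    - - 419.06
      - 205.20000000000002
    - - 491.94000000000005
      - 205.20000000000002
    - - 491.94000000000005
      - 292.40999999999997
    - - 419.06
      - 292.40999999999997
  ROI4:
    name: left_cheek
    vertices_xy:
    - - 557.532
      - 256.5
    - - 681.428
      - 256.5
    - - 681.428
      - 338.58000000000004
    - - 557.532
      - 338.58000000000004
  ROI5:
    name: chin
    vertices_xy:
    - - 389.908
      - 425.78999999999996
    - - 521.092
      - 425.78999999999996
    - - 521.092
      - 474.52500000000003
    - - 389.908
      - 474.52500000000003
  ROI6:
    name: philtrum
    vertices_xy:
    - - 429.99199999999996
      - 315.495
    - - 481.00800000000004
      - 315.495
    - - 481.00800000000004
      - 359.09999999999997
    - - 429.99199999999996
      - 359.09999999999997
  ROI7:
    name: meixin
    vertices_xy:
    - - 411.772
      - 117.99000000000001
    - - 499.22800000000007
      - 117.99000000000001
    - - 499.22800000000007
      - 164.16
    - - 411.772
      - 164.16
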