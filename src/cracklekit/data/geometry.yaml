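# Default 16-channel microphone array: 14 posterior microphones (7 per
# side, posterior surface y = -10 cm) plus one anterior microphone per
# side.  Coordinates in cm: x left(-)/right(+), y back(-)/front(+),
# z caudal(0)/cranial.  Quadrants split at z = 14 cm.
positions:
  - [-5.0, -10.0, 24.0]
  - [-11.0, -10.0, 24.0]
  - [-5.0, -10.0, 17.0]
  - [-11.0, -10.0, 17.0]
  - [-5.0, -10.0, 10.0]
  - [-11.0, -10.0, 10.0]
  - [-8.0, -10.0, 4.0]
  - [5.0, -10.0, 24.0]
  - [11.0, -10.0, 24.0]
  - [5.0, -10.0, 17.0]
  - [11.0, -10.0, 17.0]
  - [5.0, -10.0, 10.0]
  - [11.0, -10.0, 10.0]
  - [8.0, -10.0, 4.0]
  - [-8.0, 8.0, 20.0]
  - [8.0, 8.0, 20.0]
side: [left, left, left, left, left, left, left,
       right, right, right, right, right, right, right,
       left, right]
quadrant: [top-left, top-left, top-left, top-left, bottom-left, bottom-left, bottom-left,
           top-right, top-right, top-right, top-right, bottom-right, bottom-right, bottom-right,
           top-left, top-right]
sound_speed: 3.0
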