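compartments:
- ER
- cis
- med1
- med2
- med3
- med4
- med5
- TGN
- PGC
initial:
- 10.0
- 10.0
- 10.0
- 10.0
- 10.0
- 10.0
- 10.0
- 10.0
- 10.0
phases:
- - - ER
    - cis
  - - med1
    - med2
  - - med3
    - med4
  - - med5
    - TGN
- - - cis
    - med1
  - - med2
    - med3
  - - med4
    - med5
  - - TGN
    - PGC
ratio: 2.0
inversion_after: med4
clamps:
- compartment: ER
  value: 10.0
departure: null
rounds: 23
mode: integer
baseline: 10.0
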