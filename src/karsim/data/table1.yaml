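compartments:
- ER
- IC
- cis
- med1
- med2
- med3
- med4
- TGN
- PGC
initial:
- 10.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
phases:
- - - ER
    - IC
  - - cis
    - med1
  - - med2
    - med3
  - - med4
    - TGN
- - - IC
    - cis
  - - med1
    - med2
  - - med3
    - med4
  - - TGN
    - PGC
ratio: 2.0
inversion_after: null
clamps:
- compartment: ER
  value: 10.0
departure:
  compartment: PGC
  threshold_fold: 5.0
  action: remove_all
rounds: 48
mode: integer
baseline: 10.0
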