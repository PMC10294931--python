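subjects:
- Pterygoplichthys pardalis
- Macrobrachium rosenbergii
- Crassostrea gigas
- Trachemys scripta elegans
- Ambystoma mexicanum
expected_values:
  P1:
  - '3.3335'
  - '1.3334'
  - '1.3334'
  - '2.6668'
  - '0.3333'
  P2:
  - '4.3843'
  - '3.7023'
  - '3.3882'
  - '4.7456'
  - '1.6898'
  P3:
  - '1.2362'
  - '1.2362'
  - '1.2205'
  - '1.2205'
  - '1.2811'
  P4:
  - '3.9472'
  - '3.9472'
  - '3.6984'
  - '2.4676'
  - '3.1482'
  P5:
  - '1.2295'
  - '1.2965'
  - '1.2965'
  - '1.1625'
  - '1.2295'
  P6:
  - '3.4596'
  - '3.7740'
  - '2.7740'
  - '2.1572'
  - '3.2260'
  P7:
  - '3.7377'
  - '3.9314'
  - '3.4813'
  - '1.9626'
  - '2.6064'
  P8:
  - '4.5907'
  - '4.9245'
  - '3.5152'
  - '3.0000'
  - '3.9245'
  P9:
  - '4.6663'
  - '5.0000'
  - '4.0499'
  - '2.7162'
  - '3.6663'
  P10:
  - '3.8854'
  - '2.1522'
  - '2.8230'
  - '1.8230'
  - '2.0500'
  P11:
  - '3.7002'
  - '3.9770'
  - '3.3782'
  - '1.8645'
  - '2.9810'
  P12:
  - '4.6164'
  - '3.8380'
  - '2.9590'
  - '3.6722'
  - '3.1360'
  R1:
  - '3.6837'
  - '2.1230'
  - '2.0183'
  - '3.3597'
  - '0.7854'
  R2:
  - '2.8924'
  - '2.9601'
  - '2.6812'
  - '1.9539'
  - '2.4741'
  R3:
  - '3.9908'
  - '3.4341'
  - '3.2683'
  - '2.1084'
  - '2.6469'
  R4:
  - '3.8843'
  - '3.9492'
  - '3.2944'
  - '2.2260'
  - '3.0120'
  R:
  - '3.6973'
  - '2.9622'
  - '2.7073'
  - '2.5948'
  - '1.9742'
expected_grades:
  Pterygoplichthys pardalis: high
  Macrobrachium rosenbergii: medium
  Crassostrea gigas: medium
  Trachemys scripta elegans: medium
  Ambystoma mexicanum: low
source:
  scores: case-study scoring table
  expected: case-study calculation table
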