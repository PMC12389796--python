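# Healthy-control montage: 16 emitters x 8 detectors (10-5 labels),
# 33 emitter-detector channels.  The optode hardware is not mirror
# symmetric, so only 7 homotopic pairs are defined - those formed by the
# 14 channels that coincide with the clinical montage's positions.
# The adjacency is a plausible nearest-neighbor pairing (labeling only).
name: healthy33
channels:
  - FFC1h-FCC1h
  - FCC3h-FCC1h
  - CCP1h-FCC1h
  - AFF1-FCC1h
  - CCP1h-CCP3h
  - CCP5h-CCP3h
  - CPP3h-CCP3h
  - FCC3h-CCP3h
  - FCC3h-FCC5h
  - FFC5h-FCC5h
  - FTT7h-FCC5h
  - CCP5h-FCC5h
  - FFC1h-FFC3h
  - FFC5h-FFC3h
  - FCC3h-FFC3h
  - AFF1-FFC3h
  - FFC4h-FCC4h
  - FCC2h-FCC4h
  - FCC6h-FCC4h
  - CCP4h-FCC4h
  - CPP4h-FCC4h
  - CPP2h-CCP2h
  - FCC2h-CCP2h
  - CCP4h-CCP2h
  - CPP4h-CCP2h
  - AFF2-FFC2h
  - FFC4h-FFC2h
  - FCC2h-FFC2h
  - FCC6h-FFC2h
  - FCC6h-CCP6h
  - CPP6h-CCP6h
  - CCP4h-CCP6h
  - CPP4h-CCP6h
hemispheres:
  FFC1h-FCC1h: left
  FCC3h-FCC1h: left
  CCP1h-FCC1h: left
  AFF1-FCC1h: left
  CCP1h-CCP3h: left
  CCP5h-CCP3h: left
  CPP3h-CCP3h: left
  FCC3h-CCP3h: left
  FCC3h-FCC5h: left
  FFC5h-FCC5h: left
  FTT7h-FCC5h: left
  CCP5h-FCC5h: left
  FFC1h-FFC3h: left
  FFC5h-FFC3h: left
  FCC3h-FFC3h: left
  AFF1-FFC3h: left
  FFC4h-FCC4h: right
  FCC2h-FCC4h: right
  FCC6h-FCC4h: right
  CCP4h-FCC4h: right
  CPP4h-FCC4h: right
  CPP2h-CCP2h: right
  FCC2h-CCP2h: right
  CCP4h-CCP2h: right
  CPP4h-CCP2h: right
  AFF2-FFC2h: right
  FFC4h-FFC2h: right
  FCC2h-FFC2h: right
  FCC6h-FFC2h: right
  FCC6h-CCP6h: right
  CPP6h-CCP6h: right
  CCP4h-CCP6h: right
  CPP4h-CCP6h: right
symmetric_pairs:
  - [FFC1h-FCC1h, FCC2h-FFC2h]
  - [FCC3h-FCC1h, FCC2h-FCC4h]
  - [CCP1h-FCC1h, FCC2h-CCP2h]
  - [CCP1h-CCP3h, CCP4h-CCP2h]
  - [CCP5h-CCP3h, CCP4h-CCP6h]
  - [FCC3h-FCC5h, FCC6h-FCC4h]
  - [FFC1h-FFC3h, FFC4h-FFC2h]
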