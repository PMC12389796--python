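# Clinical motor-cortex montage: 14 emitters (760/850 nm) x 8 detectors,
# 28 emitter-detector channels in 14 homotopic (left/right) pairs.
# Channel id = "EMITTER-DETECTOR" (10-20 labels). The emitter-detector
# adjacency is a plausible nearest-neighbor pairing for these optode
# positions; only the labeling and the pair map matter downstream.
name: clinical28
channels:
  - F3-FC3
  - FC5-FC3
  - FC1-FC3
  - C3-FC3
  - FC5-C5
  - C3-C5
  - CP5-C5
  - FC1-C1
  - C3-C1
  - CP1-C1
  - C3-CP3
  - CP5-CP3
  - CP1-CP3
  - P3-CP3
  - F4-FC4
  - FC6-FC4
  - FC2-FC4
  - C4-FC4
  - FC6-C6
  - C4-C6
  - CP6-C6
  - FC2-C2
  - C4-C2
  - CP2-C2
  - C4-CP4
  - CP6-CP4
  - CP2-CP4
  - P4-CP4
hemispheres:
  F3-FC3: left
  FC5-FC3: left
  FC1-FC3: left
  C3-FC3: left
  FC5-C5: left
  C3-C5: left
  CP5-C5: left
  FC1-C1: left
  C3-C1: left
  CP1-C1: left
  C3-CP3: left
  CP5-CP3: left
  CP1-CP3: left
  P3-CP3: left
  F4-FC4: right
  FC6-FC4: right
  FC2-FC4: right
  C4-FC4: right
  FC6-C6: right
  C4-C6: right
  CP6-C6: right
  FC2-C2: right
  C4-C2: right
  CP2-C2: right
  C4-CP4: right
  CP6-CP4: right
  CP2-CP4: right
  P4-CP4: right
symmetric_pairs:
  - [F3-FC3, F4-FC4]
  - [FC5-FC3, FC6-FC4]
  - [FC1-FC3, FC2-FC4]
  - [C3-FC3, C4-FC4]
  - [FC5-C5, FC6-C6]
  - [C3-C5, C4-C6]
  - [CP5-C5, CP6-C6]
  - [FC1-C1, FC2-C2]
  - [C3-C1, C4-C2]
  - [CP1-C1, CP2-C2]
  - [C3-CP3, C4-CP4]
  - [CP5-CP3, CP6-CP4]
  - [CP1-CP3, CP2-CP4]
  - [P3-CP3, P4-CP4]
positions:  # schematic 2-D layout (x: left<0<right, y: posterior<0<anterior)
  F3-FC3: [-0.43, 0.60]
  FC5-FC3: [-0.58, 0.43]
  FC1-FC3: [-0.33, 0.43]
  C3-FC3: [-0.45, 0.20]
  FC5-C5: [-0.73, 0.23]
  C3-C5: [-0.60, 0.00]
  CP5-C5: [-0.73, -0.23]
  FC1-C1: [-0.18, 0.23]
  C3-C1: [-0.30, 0.00]
  CP1-C1: [-0.18, -0.23]
  C3-CP3: [-0.45, -0.20]
  CP5-CP3: [-0.58, -0.43]
  CP1-CP3: [-0.33, -0.43]
  P3-CP3: [-0.43, -0.60]
  F4-FC4: [0.43, 0.60]
  FC6-FC4: [0.58, 0.43]
  FC2-FC4: [0.33, 0.43]
  C4-FC4: [0.45, 0.20]
  FC6-C6: [0.73, 0.23]
  C4-C6: [0.60, 0.00]
  CP6-C6: [0.73, -0.23]
  FC2-C2: [0.18, 0.23]
  C4-C2: [0.30, 0.00]
  CP2-C2: [0.18, -0.23]
  C4-CP4: [0.45, -0.20]
  CP6-CP4: [0.58, -0.43]
  CP2-CP4: [0.33, -0.43]
  P4-CP4: [0.43, -0.60]
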