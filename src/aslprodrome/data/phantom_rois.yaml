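rois:
- name: meta
  role: meta
  spheres:
  - center_mm:
    - 107.1
    - 41.72866668859554
    - 74.52378471651157
    radius_mm: 15.600000000000001
  - center_mm:
    - 157.3642521546531
    - 85.27473261705852
    - 77.65117016890903
    radius_mm: 15.600000000000001
  - center_mm:
    - 56.835747845346894
    - 85.27473261705852
    - 77.65117016890903
    radius_mm: 15.600000000000001
  - center_mm:
    - 163.5992988487876
    - 92.56216871727102
    - 42.39944726492107
    radius_mm: 15.600000000000001
  - center_mm:
    - 50.60070115121237
    - 92.56216871727102
    - 42.39944726492107
    radius_mm: 15.600000000000001
- name: control
  role: control
  spheres:
  - center_mm:
    - 107.1
    - 39.488963375109094
    - 43.17168968153774
    radius_mm: 10.799999999999999
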