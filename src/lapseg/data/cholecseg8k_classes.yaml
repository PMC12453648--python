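# Class map for CholecSeg8k annotation masks.
#
# `value` is the raw grayscale pixel code stored in the *_endo_mask.png
# annotation masks; `id` is the contiguous training label. The codes are
# dataset-defined conventions, not part of the method, so this file is
# shipped as editable configuration. Exactly one class must be flagged
# as background and it must carry id 0.
classes:
  - {value: 50, id: 0,  name: black_background, background: true}
  - {value: 11, id: 1,  name: abdominal_wall}
  - {value: 21, id: 2,  name: liver}
  - {value: 13, id: 3,  name: gastrointestinal_tract}
  - {value: 12, id: 4,  name: fat}
  - {value: 31, id: 5,  name: grasper}
  - {value: 23, id: 6,  name: connective_tissue}
  - {value: 24, id: 7,  name: blood}
  - {value: 25, id: 8,  name: cystic_duct}
  - {value: 32, id: 9,  name: l_hook_electrocautery}
  - {value: 22, id: 10, name: gallbladder}
  - {value: 33, id: 11, name: hepatic_vein}
  - {value: 5,  id: 12, name: liver_ligament}
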