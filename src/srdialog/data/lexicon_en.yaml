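- code: RID13173
  preferred_label: normal
  synonyms:
  - normal
  - unremarkable
  - regular
  locale: en
  semantic_role: modifier
- code: RID28453
  preferred_label: abnormal
  synonyms:
  - abnormal
  - pathological
  locale: en
  semantic_role: modifier
- code: RID4994
  preferred_label: calculus
  synonyms:
  - calculus
  - calculi
  - stone
  - stones
  - concretion
  - concretions
  - concrement
  - concrements
  - nephrolith
  - kidney stone
  - kidney stones
  - urolith
  locale: en
  semantic_role: finding
- code: RID34394
  preferred_label: obstructive uropathy
  synonyms:
  - obstructive uropathy
  - urinary obstruction
  - hydronephrosis
  - obstruction of urinary outflow
  locale: en
  semantic_role: finding
- code: RID28473
  preferred_label: absent
  synonyms:
  - absent
  locale: en
  semantic_role: modifier
- code: RID29662
  preferred_label: right kidney
  synonyms:
  - right kidney
  locale: en
  semantic_role: anatomy
  section_id: right_kidney
- code: RID29663
  preferred_label: left kidney
  synonyms:
  - left kidney
  locale: en
  semantic_role: anatomy
  section_id: left_kidney
- code: RID30844
  preferred_label: right ureter
  synonyms:
  - right ureter
  locale: en
  semantic_role: anatomy
  section_id: right_ureter
- code: RID30845
  preferred_label: left ureter
  synonyms:
  - left ureter
  locale: en
  semantic_role: anatomy
  section_id: left_ureter
- code: RID237
  preferred_label: urinary bladder
  synonyms:
  - urinary bladder
  - bladder
  locale: en
  semantic_role: anatomy
  section_id: urinary_bladder
- code: RID50231
  preferred_label: round
  synonyms:
  - round
  - rounded
  locale: en
  semantic_role: morphology
- code: RID50233
  preferred_label: staghorn
  synonyms:
  - staghorn
  - staghorn configuration
  locale: en
  semantic_role: morphology
- code: RID50234
  preferred_label: irregular
  synonyms:
  - irregular
  - irregularly shaped
  locale: en
  semantic_role: morphology
- code: RID50241
  preferred_label: upper calyx
  synonyms:
  - upper calyx
  - upper pole calyx
  locale: en
  semantic_role: location
- code: RID50242
  preferred_label: middle calyx
  synonyms:
  - middle calyx
  - mid calyx
  locale: en
  semantic_role: location
- code: RID50243
  preferred_label: lower calyx
  synonyms:
  - lower calyx
  - lower pole calyx
  locale: en
  semantic_role: location
- code: RID50244
  preferred_label: renal pelvis
  synonyms:
  - renal pelvis
  - pyelon
  locale: en
  semantic_role: location
- code: RID50271
  preferred_label: proximal ureter
  synonyms:
  - proximal segment
  - proximal ureter
  - proximal third
  locale: en
  semantic_role: location
- code: RID50273
  preferred_label: distal ureter
  synonyms:
  - distal segment
  - distal ureter
  - distal third
  locale: en
  semantic_role: location
- code: RIDE0003
  preferred_label: ureterovesical junction
  synonyms:
  - ureterovesical junction
  - uvj
  locale: en
  semantic_role: location
- code: RID50277
  preferred_label: trigone
  synonyms:
  - trigone
  - bladder trigone
  locale: en
  semantic_role: location
- code: RID50278
  preferred_label: bladder dome
  synonyms:
  - bladder dome
  - dome of the bladder
  locale: en
  semantic_role: location
- code: RID50251
  preferred_label: grade I uropathy
  synonyms:
  - grade i
  - grade 1
  - first degree
  locale: en
  semantic_role: grade
- code: RID50252
  preferred_label: grade II uropathy
  synonyms:
  - grade ii
  - grade 2
  - second degree
  locale: en
  semantic_role: grade
- code: RID50253
  preferred_label: grade III uropathy
  synonyms:
  - grade iii
  - grade 3
  - third degree
  locale: en
  semantic_role: grade
- code: RID50254
  preferred_label: grade IV uropathy
  synonyms:
  - grade iv
  - grade 4
  - fourth degree
  locale: en
  semantic_role: grade
- code: RIDE0004
  preferred_label: parenchymal thinning
  synonyms:
  - parenchymal thinning
  - thinned parenchyma
  - parenchymal atrophy
  locale: en
  semantic_role: modifier
- code: RID50265
  preferred_label: perirenal stranding
  synonyms:
  - perirenal stranding
  - perirenal fat stranding
  - fat stranding
  locale: en
  semantic_role: modifier
- code: RIDE0001
  preferred_label: perirenal space unremarkable
  synonyms:
  - perirenal space unremarkable
  - clear perirenal space
  locale: en
  semantic_role: modifier
- code: RID50276
  preferred_label: wall thickening
  synonyms:
  - wall thickening
  - thickened wall
  - wall thickened
  locale: en
  semantic_role: modifier
- code: RID50279
  preferred_label: bladder catheter
  synonyms:
  - catheter
  - foley catheter
  - bladder catheter
  locale: en
  semantic_role: modifier
- code: RIDE0002
  preferred_label: grade of uropathy
  synonyms:
  - grade of uropathy
  - uropathy grade
  locale: en
  semantic_role: grade
- code: RIDE0005
  preferred_label: no pathologies
  synonyms:
  - no pathologies
  - no pathology
  - no abnormalities
  - no abnormality
  - no pathological findings
  locale: en
  semantic_role: modifier
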