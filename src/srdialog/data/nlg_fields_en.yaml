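codes:
  RID13173: normal
  RID28453: abnormal
  RID28473: absent
  RID34394: obstructive uropathy
  RID50231: round
  RID50233: staghorn
  RID50234: irregular
  RID50241: upper calyx
  RID50242: middle calyx
  RID50243: lower calyx
  RID50244: renal pelvis
  RID50251: grade I
  RID50252: grade II
  RID50253: grade III
  RID50254: grade IV
  RID50265: perirenal fat stranding
  RID50271: proximal ureter
  RID50273: distal ureter
  RID50276: wall thickening
  RID50277: trigone
  RID50278: bladder dome
  RID50279: indwelling catheter
  RIDE0003: ureterovesical junction
  RIDE0004: parenchymal thinning
fields:
  left_kidney_calculus_count: 'left kidney: Number of calculi'
  left_kidney_calculus_density: 'left kidney: Density of largest calculus'
  left_kidney_calculus_location: 'left kidney: Location of largest calculus'
  left_kidney_calculus_morphology: 'left kidney: Morphology of largest calculus'
  left_kidney_calculus_size: 'left kidney: Size of largest calculus'
  left_kidney_obstructive_uropathy: 'left kidney: Obstructive uropathy'
  left_kidney_parenchyma: 'left kidney: Parenchyma'
  left_kidney_perirenal_space: 'left kidney: Perirenal space'
  left_kidney_status: 'left kidney: Status'
  left_kidney_uropathy_grade: 'left kidney: Grade of uropathy'
  left_ureter_calculus_count: 'left ureter: Number of calculi'
  left_ureter_calculus_density: 'left ureter: Density of largest calculus'
  left_ureter_calculus_size: 'left ureter: Size of largest calculus'
  left_ureter_obstructive_uropathy: 'left ureter: Obstructive uropathy'
  left_ureter_segment_location: 'left ureter: Segment of largest calculus'
  left_ureter_status: 'left ureter: Status'
  left_ureter_wall: 'left ureter: Ureteral wall'
  right_kidney_calculus_count: 'right kidney: Number of calculi'
  right_kidney_calculus_density: 'right kidney: Density of largest calculus'
  right_kidney_calculus_location: 'right kidney: Location of largest calculus'
  right_kidney_calculus_morphology: 'right kidney: Morphology of largest calculus'
  right_kidney_calculus_size: 'right kidney: Size of largest calculus'
  right_kidney_obstructive_uropathy: 'right kidney: Obstructive uropathy'
  right_kidney_parenchyma: 'right kidney: Parenchyma'
  right_kidney_perirenal_space: 'right kidney: Perirenal space'
  right_kidney_status: 'right kidney: Status'
  right_kidney_uropathy_grade: 'right kidney: Grade of uropathy'
  right_ureter_calculus_count: 'right ureter: Number of calculi'
  right_ureter_calculus_density: 'right ureter: Density of largest calculus'
  right_ureter_calculus_size: 'right ureter: Size of largest calculus'
  right_ureter_obstructive_uropathy: 'right ureter: Obstructive uropathy'
  right_ureter_segment_location: 'right ureter: Segment of largest calculus'
  right_ureter_status: 'right ureter: Status'
  right_ureter_wall: 'right ureter: Ureteral wall'
  urinary_bladder_calculus_count: 'urinary bladder: Number of calculi'
  urinary_bladder_calculus_density: 'urinary bladder: Density of largest calculus'
  urinary_bladder_calculus_location: 'urinary bladder: Location of largest calculus'
  urinary_bladder_calculus_size: 'urinary bladder: Size of largest calculus'
  urinary_bladder_other_findings: 'urinary bladder: Other findings'
  urinary_bladder_status: 'urinary bladder: Status'
  urinary_bladder_wall: 'urinary bladder: Bladder wall'
locale: en
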