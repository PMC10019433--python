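locale: en
mappings:
  ask_additional_findings: Are there additional findings in the {section}?
  ask_clinical_history: Is the clinical history relevant here?
  ask_count_left_kidney: Uropathy is present — how many calculi are in the left kidney?
  ask_count_left_ureter: Uropathy is present — how many calculi are in the left ureter?
  ask_count_right_kidney: Uropathy is present — how many calculi are in the right kidney?
  ask_count_right_ureter: Uropathy is present — how many calculi are in the right ureter?
  ask_density_left_kidney: What is the density of the largest calculus in the left kidney?
  ask_density_left_ureter: What is the density of the largest calculus in the left ureter?
  ask_density_right_kidney: What is the density of the largest calculus in the right kidney?
  ask_density_right_ureter: What is the density of the largest calculus in the right ureter?
  ask_density_urinary_bladder: What is the density of the largest calculus in the urinary bladder?
  ask_grade_left_kidney: What is the grade of uropathy of the left kidney?
  ask_grade_right_kidney: What is the grade of uropathy of the right kidney?
  ask_location_left_kidney: Where is the largest calculus in the left kidney located?
  ask_location_right_kidney: Where is the largest calculus in the right kidney located?
  ask_location_urinary_bladder: Where in the urinary bladder is the largest calculus located?
  ask_morphology_left_kidney: What is the morphology of the largest calculus in the left kidney?
  ask_morphology_right_kidney: What is the morphology of the largest calculus in the right kidney?
  ask_obstructive_uropathy_left_kidney: Is there obstructive uropathy of the left kidney?
  ask_obstructive_uropathy_left_ureter: Is there obstructive uropathy of the left ureter?
  ask_obstructive_uropathy_right_kidney: Is there obstructive uropathy of the right kidney?
  ask_obstructive_uropathy_right_ureter: Is there obstructive uropathy of the right ureter?
  ask_other_urinary_bladder: Are there further findings in the urinary bladder?
  ask_overall_impression: Please dictate an overall impression.
  ask_parenchyma_left_kidney: Please describe the parenchyma of the left kidney.
  ask_parenchyma_right_kidney: Please describe the parenchyma of the right kidney.
  ask_perirenal_left_kidney: Please describe the perirenal space of the left kidney.
  ask_perirenal_right_kidney: Please describe the perirenal space of the right kidney.
  ask_prior_comparison: Is there a prior examination to compare with?
  ask_report_complete: The template is complete — finish the report?
  ask_segment_left_ureter: In which segment of the left ureter is the largest calculus?
  ask_segment_right_ureter: In which segment of the right ureter is the largest calculus?
  ask_size_left_kidney: What is the size of the largest calculus in the left kidney?
  ask_size_left_ureter: What is the size of the largest calculus in the left ureter?
  ask_size_right_kidney: What is the size of the largest calculus in the right kidney?
  ask_size_right_ureter: What is the size of the largest calculus in the right ureter?
  ask_size_urinary_bladder: What is the size of the largest calculus in the urinary bladder?
  ask_status_left_kidney: What is the overall status of the left kidney?
  ask_status_right_kidney: What is the overall status of the right kidney?
  ask_wall_left_ureter: Please describe the wall of the left ureter.
  ask_wall_right_ureter: Please describe the wall of the right ureter.
  ask_wall_urinary_bladder: Please describe the bladder wall.
  confirm_calculus_left_kidney: You mentioned a possible calculus in the left kidney — can you confirm
    it?
  confirm_calculus_left_ureter: You mentioned a possible calculus in the left ureter — can you confirm
    it?
  confirm_calculus_right_kidney: You mentioned a possible calculus in the right kidney — can you confirm
    it?
  confirm_calculus_right_ureter: You mentioned a possible calculus in the right ureter — can you confirm
    it?
  confirm_calculus_urinary_bladder: You mentioned a possible calculus in the urinary bladder — can you
    confirm it?
  confirm_no_pathologies_left_kidney: 'Confirm: no pathologies of the left kidney?'
  confirm_no_pathologies_left_ureter: 'Confirm: no pathologies of the left ureter?'
  confirm_no_pathologies_right_kidney: 'Confirm: no pathologies of the right kidney?'
  confirm_no_pathologies_right_ureter: 'Confirm: no pathologies of the right ureter?'
  confirm_no_pathologies_urinary_bladder: 'Confirm: no pathologies of the urinary bladder?'
  notify_section_complete_left_kidney: The left kidney is complete; moving on to the next organ system.
  notify_section_complete_left_ureter: The left ureter is complete; moving on to the next organ system.
  notify_section_complete_right_kidney: The right kidney is complete; moving on to the next organ system.
  notify_section_complete_right_ureter: The right ureter is complete; moving on to the next organ system.
  notify_section_complete_urinary_bladder: The urinary bladder is complete; moving on to the next organ
    system.
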