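# Small German sample lexicon: enough concepts to run the worked example in
# the de locale; the full shipped knowledgebase is the English one.
- code: RID4994
  preferred_label: Konkrement
  synonyms: [konkrement, konkremente, stein, steine, nierenstein, nierensteine]
  locale: de
  semantic_role: finding
- code: RID34394
  preferred_label: Harnstauung
  synonyms: [harnstauung, obstruktive uropathie, hydronephrose, harnaufstau]
  locale: de
  semantic_role: finding
- code: RID28453
  preferred_label: pathologisch
  synonyms: [pathologisch, auffällig]
  locale: de
  semantic_role: modifier
- code: RID13173
  preferred_label: unauffällig
  synonyms: [unauffällig, regelrecht]
  locale: de
  semantic_role: modifier
- code: RIDE0005
  preferred_label: keine Pathologien
  synonyms: [keine pathologien, keine pathologie, keine auffälligkeiten]
  locale: de
  semantic_role: modifier
- code: RID29662
  preferred_label: rechte Niere
  synonyms: [rechte niere, rechten niere]
  locale: de
  semantic_role: anatomy
  section_id: right_kidney
- code: RID29663
  preferred_label: linke Niere
  synonyms: [linke niere, linken niere]
  locale: de
  semantic_role: anatomy
  section_id: left_kidney
- code: RID237
  preferred_label: Harnblase
  synonyms: [harnblase, blase]
  locale: de
  semantic_role: anatomy
  section_id: urinary_bladder
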