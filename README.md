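# srdialog

A stateless dialogue engine that converts free-text radiology dictation into
a coded structured report (SR), detects missing findings with a rule
knowledgebase, and answers with natural-language advice.

Structured reporting is strongly recommended in radiology, but templates are
usually filled with mouse and keyboard while radiologists dictate free text
through speech recognition. `srdialog` bridges the two: a dictated utterance
is analyzed by an NLP pipeline (sentence segmentation with organ-section
attribution, dictionary-based concept matching against a RadLex-style
lexicon, trigger-scope negation/speculation detection, measurement
normalization), converted into *template intents* (field assignments) and
*advice intents* (questions about missing findings) by a decision-table
dialogue manager, and rendered back to the user. The engine is a pure
function of its inputs — the same state and text always produce the same
result — so it can back a stateless web service.

The shipped use case is unenhanced CT for urolithiasis: a 41-field template
over five organ systems (right kidney, right ureter, left kidney, left
ureter, urinary bladder), an 85-rule knowledgebase, a concept lexicon with 5
local RadLex extensions (RIDE codes), 57 advice-to-question mappings and 65
field/code verbalizations.

## The pipeline

For a turn with state *s* and utterance *u*:

1. **extract** — `extract_structured(u, focus, lexicon)` yields concept
   mentions per organ section, each with a status
   (affirmed/negated/speculated) from a NegEx-style trigger-scope model
   (scope ≤ 6 tokens, nearest trigger wins, pseudo-triggers like "no change"
   block), plus normalized counts ("two" → 2), sizes ("0.7 cm" → 7 mm,
   "10 × 8 × 6 mm" → 10 mm) and densities ("900 HU").
2. **detect intents** — affirmed mentions fill fields; negated mentions
   store the field's normal/absent value; speculated mentions fill but are
   marked uncertain (configurable). Template-intent confidence equals the
   template's completeness (the fraction of *currently required* fields
   filled); advice rules whose conditions hold emit advice intents with
   their rule prior as confidence.
3. **forward chaining** — `implicit_set` rules run to a fixpoint (e.g. a
   documented calculus marks the kidney abnormal); implicit values never
   override explicit ones.
4. **advice filtering and NLG** — advice intents below the confidence
   threshold (default 0.5) are dropped; the rest are rendered to questions.

Evaluation follows an entity-level protocol: predicted and gold states are
compared per field, TP/FP/FN are pooled over all reports and fields
(micro-averaging), and precision, recall and F1 = 2PR/(P+R) are computed. A
synthetic report generator produces gold-labeled corpora, including three
documented hard cases (wrong-organ distractor sentences, three-dimensional
sizes, bare singular "calculus" without a count).

## Worked example

```python
import srdialog as sd

spec = sd.urolithiasis_template()
lex = sd.default_lexicon()
rules = sd.default_rules()

result = sd.process_turn(
    sd.empty_state(spec),
    "Two calculi in the right kidney.",
    "right_kidney", spec, lex, rules,
    advice_mappings=sd.default_advice_mappings(),
)
print(result.new_state.value_of("right_kidney_status"))
print(result.new_state.values["right_kidney_calculus_count"].value,
      result.new_state.values["right_kidney_calculus_count"].verbatim_text)
print(result.advice_texts[0])
```

prints

```
RID28453
2 Two
Is there obstructive uropathy of the right kidney?
```

The kidney is coded abnormal (RID28453) because a calculus (RID4994) was
documented — an implicit rule, not a dictated statement; the count is stored
as the number 2 together with its dictated surface form; and because no
statement about obstruction was made, the highest-priority advice asks about
obstructive uropathy (RID34394). The same call from the same state always
returns the identical result.

The CLI mirrors the library:

```sh
srdialog turn --text "Two calculi in the right kidney." --focus right_kidney
srdialog gen --kind right-kidney --n 50 --seed 0 --out corpus.jsonl
srdialog eval --corpus corpus.jsonl --fields right_kidney:eval
```

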