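# Methods

## Problem and scope

`srdialog` implements the backend of a task-oriented reporting dialogue: it
receives dictated free text (speech recognition is out of scope — text is
the input), converts it into coded assignments for a structured-report (SR)
template, derives implicit facts with a rule knowledgebase, and asks the
user about missing findings. The engine is stateless by contract: every
public operation is a pure function of its arguments, so repeated calls with
equal inputs are bit-identical. The demonstration domain is unenhanced CT
for urolithiasis.

## Template model

A template is an ordered set of sections with typed fields (`coded`,
`numeric` with unit, `count`, `free_text`). The shipped urolithiasis
template has 5 sections and 41 fields: 10 per kidney (status, number of
calculi, size/density/morphology/location of the largest calculus,
obstructive uropathy, grade of uropathy, parenchyma, perirenal space), 7 per
ureter (status, count, size, density, segment, uropathy, wall) and 7 for the
bladder (status, count, size, density, location, wall, other findings).
This allocation is a reconstruction: it contains every field the evaluation
protocol names and sums to the documented total. The grade of uropathy is
coded I–IV following common hydronephrosis grading.

Fill modes form a precedence lattice `explicit > implicit > auto_normal`;
an assignment of lower precedence never overwrites a higher one, and
assignments of equal precedence follow dictation recency (the later mention
wins). **Completeness** — which doubles as template-intent confidence — is
the fraction of *currently required* fields filled. Always-required fields
(status, count, uropathy, parenchyma/perirenal or wall/other) are in the
denominator from the start; conditional feature fields (size, density,
morphology, location, segment, grade) enter only when their activating
`require_field` rule fires, e.g. once a calculus is documented. A
`completeness_mode="all"` configuration counts all 41 fields instead.

The "no pathologies" shortcut auto-completes a section: every
always-required field receives its declared normal/absent default
(`auto_normal` mode) and the active section advances. Conditional feature
fields are deliberately left empty — they are inactive for a normal organ,
so the section still contributes completeness 1, and a "normal morphology"
for a nonexistent stone would be meaningless. Section advancement is
forward-only, mirroring the consecutive organ-by-organ reporting workflow.

## Lexicon and matching

Concepts carry a code (`RID<digits>`, or `RIDE<digits>` for local
extensions), a preferred label, synonyms and a semantic role; anatomy
concepts additionally name the template section they map to. Only the three
codes central to the use case (RID28453 abnormal, RID4994 calculus,
RID34394 obstructive uropathy) are authoritative RadLex identifiers; the
remaining RID codes are placeholders in the RadLex pattern, and the five
RIDE extensions (perirenal space unremarkable, grade of uropathy,
ureterovesical junction, parenchymal thinning, no pathologies) are
reconstructions.

Matching is dictionary-based: case-folded token sequences, leftmost-longest
with overlaps resolved longest-first (token count, then character length,
then earlier start). Inflected forms (calculus/calculi) are listed as
synonyms rather than stemmed — deterministic and locale-portable. Synonym
ambiguity (one phrase, two codes) is rejected at load time. An optional
edit-distance-1 mode (via `edlib`) tolerates dictation typos in single
tokens; it is off by default and unused in all shipped evaluations. A naive
scan oracle in the test suite certifies index/selection equivalence on 500+
randomized token sequences.

## Extraction

Sentences are split on terminal punctuation (punctuation inside decimals is
exempt) into segments that tile the utterance exactly. Each sentence is
attributed to the section of the last explicit organ mention at or before
it; with no organ mentioned so far, the dialogue focus applies. This
sentence-level rule is a reconstruction; its failure mode (a sentence about
another organ that never names it) is exactly the distractor hard case.

Negation/speculation status is a deterministic trigger-scope model rather
than a learned classifier (no weights are available, and a deterministic
model is reproducible and locale-extensible behind the same three-way
contract). Pre-triggers ("no", "without", "free of", "suspected",
"possible") scope up to 6 tokens forward, post-triggers ("absent", "cannot
be excluded") 6 tokens backward, within the sentence; triggers inside a
matched phrase ("no pathologies") are ignored; pseudo-triggers ("no
change") block. A single in-scope trigger allocates pseudo-probability 0.9
to its class and 0.05 to each other; no trigger means affirmed at 0.9. On
conflicts the nearest trigger wins, ties favouring negation. Classification
is per mention; scope length 6 and nearest-trigger resolution follow common
NegEx defaults.

Measurements are normalized to mm (sizes; cm × 10) and HU (densities);
counts come from digit tokens and number words up to twenty in both
locales. Three-dimensional strings "a × b × c mm" reduce to the largest
dimension with a `three_dimensional` provenance flag; setting
`handle_3d_sizes=False` drops them instead, emulating a strictly
one-dimensional template. Measurements attach to the nearest preceding
finding mention in the same sentence, else the nearest following — also a
reconstruction, certified by the round-trip property. A bare singular
finding noun implies count 1 when `infer_singular_count` is on (default);
the inferred count is a fallback that never overrides a dictated count.

## Dialogue management

The knowledgebase is a CSV decision table (85 rows for urolithiasis): each
rule has predicate conditions over state and current content
(`filled(f)`, `not_filled(f)`, `has(f,code)`, `num_gt(f,x)`,
`mention(code,status,section)`) and actions (`set`, `require`, `advise`,
`auto_complete`). `implicit_set` rules forward-chain to a fixpoint — each
field is set at most once per run, so termination is guaranteed, and two
rules deriving different values for one field raise an error naming both.
This replaces an ontology-reasoner design with an equivalent monotone
forward-chaining engine; at this rule count the semantics coincide and the
engine is dependency-free.

Advice intents are emitted only when *all* of a rule's conditions hold;
their confidence is the rule's prior (the satisfied-condition fraction is 1
by construction). The default filter threshold is 0.5; shipped speculative
rules with priors below it demonstrate filtering. Every advice rule
includes a `not_filled` condition on its target field, so advice never
targets filled fields. Speculated findings fill the field marked uncertain
by default (`speculation_policy="fill_uncertain"`); the `"ask"` policy
leaves the field empty and lets a confirmation rule ask instead.

## Synthetic corpus generator

The generator emulates telegraphic urolithiasis CT dictation: per organ an
opening sentence naming the organ (count + finding noun), then feature
sentences (size, density, morphology, location/segment), a uropathy
statement with optional grade, parenchyma/perirenal or wall/catheter
statements, or the "no pathologies" shortcut. Phrasings draw on the
lexicon's synonym inventory, and gold states are built alongside the text,
so labels hold by construction. Defaults: counts 1–4, sizes 3–18 mm,
densities 200–1400 HU, uropathy present half the time, number words vs
digits at 0.5, negated-phrasing rate 0.3, speculation rate 0.1 — chosen as
plausible for stone-protocol CT reporting; all are configurable. All
hard-case rates default to 0. The right-kidney protocol generator emits 50
reports with at least one right-kidney calculus and gold over exactly the
seven evaluated fields (350 value slots; the grade slot is empty when
uropathy is absent). The field-coverage suite emits two reports per field
with distinct phrasings (82 for the shipped template).

What the generator does *not* model: free word order, abbreviations,
misrecognized speech, cross-sentence coreference beyond organ carry-over,
and synonyms outside the lexicon. A perfect score on clean synthetic
corpora therefore certifies internal consistency of the pipeline (the
closed-loop property), not performance on archive reports; the hard-case
injectors exist precisely to push outside the extractor's competence and
reproduce realistic false positives/negatives:

* `distractor_organ` — a trailing sentence attributing findings to an
  unnamed other organ ("the contralateral side…"), contaminating the
  focused organ (precision and recall drop);
* `three_d_size` — with `handle_3d_sizes=False`, 3-D sizes are lost
  (recall drops);
* `singular_noun` — with `infer_singular_count=False`, "calculus" without a
  numeral leaves the count empty (recall drops).

Every injected difficulty is recorded as a flag on the report, and the
evaluation's error log carries those flags, so each error is attributable
to its mechanism.

## Evaluation

Scoring is per field value: TP for a normalized match (numeric tolerance
zero, codes exact, counts integer, text case-folded), FP for a value where
gold is empty, FN for a missed gold value; a wrong value counts as FP *and*
FN under the default strict policy (`wrong_value_policy="fp_only"` is
available — the protocol's convention in the source material is not
stated, and strict is the conservative choice). Counts are pooled across
reports and fields before computing precision, recall and F1
(micro-averaging). Zero-denominator conventions: all metrics 1.0 when
nothing was claimed and nothing was to find; a metric is 0.0 when only its
own denominator is zero. With no fixed field list, each report is scored
over the union of gold-filled and predicted-filled fields; the right-kidney
protocol fixes the seven evaluated fields.

## Numerical and design notes

* Offsets are 0-based half-open character spans; tokens are `\w+` runs.
* Status pseudo-probabilities are the fixed allocation (0.9/0.05/0.05);
  they are ranks, not calibrated probabilities.
* Problem sizes in the shipped checks — 200 generic reports, 100 reports
  per hard-case scenario, 500 matcher oracle cases — keep the full suite
  in a few seconds while leaving each property overdetermined.
* Whether the 41 fields include per-section status fields is not
  documented; this reconstruction includes them, and the seven-field
  evaluation protocol is unaffected either way.
* The per-locale data files (template, lexicon, triggers, NLG) are the
  single source of wording; the German sample lexicon and trigger set are
  small but exercise the full pipeline path.

## Known limitations

No coreference across turns (each turn re-attributes from its own organ
mentions plus focus); no statistical language understanding — an unknown
synonym is simply not matched; free-text fields are never filled from
dictation (the shipped template uses coded fields throughout); the
stateless service endpoint is a deployment pattern, not shipped
infrastructure (the CLI emits the identical JSON payload).
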