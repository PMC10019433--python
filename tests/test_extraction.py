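"""Segmentation, negation/speculation status, measurement normalization."""

import pytest

from srdialog.extraction import (
    AttributionMode,
    Status,
    Utterance,
    classify_status,
    extract_measurements,
    extract_structured,
    segment_utterance,
)


def mention_span(text, phrase):
    start = text.index(phrase)
    return (start, start + len(phrase))


class TestSegmentation:
    def test_explicit_organ_mention(self, lex):
        utt = Utterance(text="Two calculi in the right kidney.")
        segs = segment_utterance(utt, "right_kidney", lex)
        assert len(segs) == 1
        assert segs[0].section_id == "right_kidney"
        assert segs[0].attribution_mode is AttributionMode.explicit_mention

    def test_focus_fallback(self, lex):
        utt = Utterance(text="No abnormality seen.")
        segs = segment_utterance(utt, "urinary_bladder", lex)
        assert segs[0].section_id == "urinary_bladder"
        assert segs[0].attribution_mode is AttributionMode.dialogue_focus

    def test_organ_switch_between_sentences(self, lex):
        text = "Right kidney unremarkable. The left kidney shows one calculus."
        segs = segment_utterance(Utterance(text=text), "right_kidney", lex)
        assert [s.section_id for s in segs] == ["right_kidney", "left_kidney"]

    def test_carry_over_to_unnamed_sentence(self, lex):
        text = "The left ureter shows one calculus. It measures 4 mm."
        segs = segment_utterance(Utterance(text=text), "right_kidney", lex)
        assert [s.section_id for s in segs] == ["left_ureter", "left_ureter"]

    @pytest.mark.parametrize(
        "text",
        [
            "Two calculi in the right kidney. The largest measures 0.7 cm.",
            "No abnormality.",
            "",
            "One calculus. 900 HU; no uropathy! Bladder clear?",
        ],
    )
    def test_segments_tile_the_utterance(self, lex, text):
        segs = segment_utterance(Utterance(text=text), "right_kidney", lex)
        rebuilt = "".join(text[s.start : s.end] for s in segs)
        assert rebuilt == text
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start


class TestStatus:
    @pytest.mark.parametrize(
        "text,phrase,expected",
        [
            ("No calculus in the left ureter", "calculus", Status.negated),
            ("Suspected obstructive uropathy", "obstructive uropathy",
             Status.speculated),
            ("Two calculi in the right kidney", "calculi", Status.affirmed),
            ("Without perirenal stranding", "perirenal stranding",
             Status.negated),
            ("A calculus cannot be excluded", "calculus", Status.speculated),
            ("Obstructive uropathy is excluded", "Obstructive uropathy",
             Status.negated),
            ("No change, one calculus as before", "calculus",
             Status.affirmed),  # pseudo-trigger blocks "no"
        ],
    )
    def test_trigger_scope(self, triggers, text, phrase, expected):
        scores = classify_status(text, mention_span(text, phrase), triggers)
        assert max(scores, key=scores.get) == expected.value
        assert scores[expected.value] == pytest.approx(0.9)
        assert sum(scores.values()) == pytest.approx(1.0)

    def test_scope_is_limited_to_six_tokens(self, triggers):
        text = "No dilatation of one the two the three the four calculus"
        scores = classify_status(
            text, mention_span(text, "calculus"), triggers
        )
        assert max(scores, key=scores.get) == "affirmed"

    def test_nearest_trigger_wins(self, triggers):
        text = "No evidence of obstruction but suspected calculus"
        scores = classify_status(
            text, mention_span(text, "calculus"), triggers
        )
        assert max(scores, key=scores.get) == "speculated"


class TestMeasurements:
    def test_number_word_count(self):
        (m,) = extract_measurements("two calculi")
        assert m.kind.value == "count" and m.value == 2 and m.verbatim == "two"

    def test_cm_to_mm(self):
        (m,) = extract_measurements("0.7 cm")
        assert m.kind.value == "size" and m.value == 7.0 and m.unit == "mm"

    def test_density(self):
        (m,) = extract_measurements("density 900 HU")
        assert m.kind.value == "density" and m.value == 900.0

    @pytest.mark.parametrize(
        "dims,unit,factor",
        [((10, 8, 6), "mm", 1), ((3, 12, 7), "mm", 1), ((1, 2, 3), "cm", 10)],
    )
    def test_3d_reduces_to_max_dimension(self, dims, unit, factor):
        text = " × ".join(str(d) for d in dims) + f" {unit}"
        (m,) = extract_measurements(text)
        assert m.value == max(d * factor for d in dims)  # oracle: explicit max
        assert "three_dimensional" in m.flags

    def test_3d_dropped_when_disabled(self):
        out = extract_measurements("10 x 8 x 6 mm", handle_3d_sizes=False)
        assert out == []

    def test_malformed_numerals_skipped(self):
        assert extract_measurements("about so-many mm of nothing..") == []

    def test_german_number_words(self):
        (m,) = extract_measurements("zwei Konkremente", locale="de")
        assert m.value == 2

    def test_excluded_spans_never_yield_counts(self):
        out = extract_measurements("grade 2", exclude=[(0, 7)])
        assert out == []


class TestExtractStructured:
    def test_worked_example(self, lex):
        utt = Utterance(text="Two calculi in the right kidney.")
        content = extract_structured(utt, "right_kidney", lex)
        (m,) = content.mentions["right_kidney"]
        assert m.code == "RID4994"
        assert m.status is Status.affirmed
        assert m.count == 2 and m.count_verbatim.lower() == "two"

    def test_empty_text(self, lex):
        content = extract_structured(Utterance(text=""), "right_kidney", lex)
        assert content.is_empty

    def test_feature_sentence_attachment(self, lex):
        text = (
            "One 7 mm calculus, 900 HU, in the lower calyx, "
            "no obstructive uropathy."
        )
        content = extract_structured(
            Utterance(text=text), "right_kidney", lex
        )
        by_code = {m.code: m for m in content.mentions["right_kidney"]}
        calc = by_code["RID4994"]
        assert calc.status is Status.affirmed
        assert calc.count == 1
        assert calc.size_mm == 7.0
        assert calc.density_hu == 900.0
        assert "RID50243" in by_code  # lower calyx
        assert by_code["RID34394"].status is Status.negated

    def test_pure_function_of_inputs(self, lex):
        utt = Utterance(text="Two calculi in the right kidney. 7 mm.")
        first = extract_structured(utt, "right_kidney", lex)
        for _ in range(5):
            assert extract_structured(utt, "right_kidney", lex) == first

    def test_status_scores_invariants_hold_everywhere(self, lex):
        texts = [
            "No calculus. Suspected obstructive uropathy. Two stones.",
            "Without wall thickening; catheter in place.",
            "Possible staghorn calculus in the renal pelvis.",
        ]
        for text in texts:
            content = extract_structured(
                Utterance(text=text), "right_kidney", lex
            )
            for _, m in content.all_mentions():
                assert sum(m.status_scores.values()) == pytest.approx(1.0)
                top = max(m.status_scores, key=m.status_scores.get)
                assert top == m.status.value

    def test_trailing_other_organ_sentence_is_isolated(self, lex):
        base = "Two calculi in the right kidney."
        extended = base + " The urinary bladder shows wall thickening."
        a = extract_structured(Utterance(text=base), "right_kidney", lex)
        b = extract_structured(Utterance(text=extended), "right_kidney", lex)
        assert a.mentions["right_kidney"] == b.mentions["right_kidney"]

    def test_german_locale(self, lex):
        import srdialog as sd

        lexde = sd.default_lexicon("de")
        trg = sd.default_trigger_set("de")
        content = extract_structured(
            Utterance(
                text="Zwei Konkremente in der rechten Niere. "
                "Keine Harnstauung.",
                locale="de",
            ),
            "right_kidney",
            lexde,
            trg,
        )
        by_code = {m.code: m for m in content.mentions["right_kidney"]}
        assert by_code["RID4994"].count == 2
        assert by_code["RID34394"].status is Status.negated
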