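"""Dialogue manager: rules, intents, forward chaining, turn processing."""

import pytest

import srdialog as sd
from srdialog.config import EngineConfig
from srdialog.dialogue import (
    Intent,
    RuleError,
    RuleKind,
    apply_rules_fixpoint,
    detect_intents,
    filter_advice,
    load_rules,
    process_turn,
)
from srdialog.extraction import Utterance, extract_structured
from srdialog.template import FillMode, completeness, empty_state, set_field


def naive_fixpoint(state, rules, spec):
    """Oracle: repeatedly apply single passes of implicit rules until stable,
    without the engine's bookkeeping."""
    from srdialog.template import set_field as sf

    while True:
        before = state
        for rule in sorted(
            (r for r in rules if r.kind is RuleKind.implicit_set),
            key=lambda r: (-r.priority, r.rule_id),
        ):
            if rule.conditions_hold(state, None):
                for act in rule.actions:
                    if act.name == "set":
                        fid, raw = act.args
                        existing = state.values.get(fid)
                        if existing is not None and existing.fill_mode in (
                            FillMode.explicit,
                            FillMode.implicit,
                        ):
                            continue
                        from srdialog.dialogue import _coerce_rule_value

                        state = sf(
                            state, spec, fid, _coerce_rule_value(spec, fid, raw),
                            fill_mode=FillMode.implicit, rule_id=rule.rule_id,
                        )
        if state == before:
            return state


class TestLoadRules:
    def test_shipped_knowledgebase_has_85_rules(self, rules):
        assert len(rules) == 85

    def test_empty_table_is_valid(self):
        assert load_rules([]) == ()

    def test_unknown_field_reference_rejected(self, spec):
        rows = [
            {
                "rule_id": "bad",
                "kind": "implicit_set",
                "conditions": "filled(not_a_field)",
                "actions": "set(right_kidney_status,RID28453)",
            }
        ]
        with pytest.raises(RuleError, match="bad"):
            load_rules(rows, spec)

    def test_rule_cannot_set_and_require_same_field(self, spec):
        rows = [
            {
                "rule_id": "conflicted",
                "kind": "implicit_set",
                "conditions": "filled(right_kidney_calculus_count)",
                "actions": "set(right_kidney_status,RID28453); "
                "require(right_kidney_status)",
            }
        ]
        with pytest.raises(RuleError, match="conflicted"):
            load_rules(rows, spec)

    def test_advice_rules_all_have_nlg_mappings(self, rules, advice_mappings):
        from srdialog.dialogue import check_advice_coverage

        check_advice_coverage(rules, advice_mappings)


class TestDetectIntents:
    def test_two_calculi_example(self, spec, lex, rules, blank):
        content = extract_structured(
            Utterance(text="Two calculi in the right kidney."),
            "right_kidney",
            lex,
        )
        intents = detect_intents(content, blank, rules, spec)
        template = [i for i in intents if i.kind == "template"]
        advice = [i for i in intents if i.kind == "advice"]
        assert template[0].slots["right_kidney_calculus_count"] == 2
        uropathy = [
            i for i in advice
            if i.intent_id == "ask_obstructive_uropathy_right_kidney"
        ]
        assert uropathy and uropathy[0].slots["concept"] == "RID34394"

    def test_empty_content_no_template_intents(self, spec, lex, rules, blank):
        content = extract_structured(
            Utterance(text=""), "right_kidney", lex
        )
        intents = detect_intents(content, blank, rules, spec)
        assert [i for i in intents if i.kind == "template"] == []

    def test_negated_finding_stores_absent_value(self, spec, lex, rules, blank):
        content = extract_structured(
            Utterance(text="No calculi in the right kidney."),
            "right_kidney",
            lex,
        )
        (intent,) = [
            i for i in detect_intents(content, blank, rules, spec)
            if i.kind == "template"
        ]
        assert intent.slots["right_kidney_calculus_count"] == 0

    def test_speculated_finding_marked_uncertain(self, spec, lex, rules, blank):
        content = extract_structured(
            Utterance(text="Suspected obstructive uropathy of the right kidney."),
            "right_kidney",
            lex,
        )
        (intent,) = [
            i for i in detect_intents(content, blank, rules, spec)
            if i.kind == "template" and i.slots
        ]
        assert "right_kidney_obstructive_uropathy" in intent.uncertain_slots

    def test_speculation_ask_policy_leaves_field_empty(
        self, spec, lex, rules, blank
    ):
        cfg = EngineConfig(speculation_policy="ask")
        result = process_turn(
            blank,
            "Suspected calculus in the right kidney.",
            "right_kidney",
            spec,
            lex,
            rules,
            cfg,
        )
        assert not result.new_state.filled("right_kidney_calculus_count")
        assert any(
            i.intent_id == "confirm_calculus_right_kidney"
            for i in result.advice_intents
        )


class TestFixpoint:
    def test_calculus_implies_abnormal(self, spec, rules, blank):
        state = set_field(blank, spec, "right_kidney_calculus_count", 2)
        out = apply_rules_fixpoint(state, rules, spec)
        fv = out.values["right_kidney_status"]
        assert fv.value == "RID28453"
        assert fv.fill_mode is FillMode.implicit
        assert fv.rule_id == "right_kidney_imp_abnormal_calc"

    def test_empty_state_unchanged(self, spec, rules, blank):
        assert apply_rules_fixpoint(blank, rules, spec) == blank

    def test_chain_grade_to_uropathy_to_abnormal(self, spec, rules, blank):
        state = set_field(blank, spec, "right_kidney_uropathy_grade", "RID50252")
        out = apply_rules_fixpoint(state, rules, spec)
        assert out.value_of("right_kidney_obstructive_uropathy") == "RID34394"
        assert out.value_of("right_kidney_status") == "RID28453"

    @pytest.mark.parametrize(
        "seed_fields",
        [
            [("right_kidney_calculus_count", 3)],
            [("right_kidney_uropathy_grade", "RID50251")],
            [("urinary_bladder_wall", "RID50276"),
             ("left_kidney_parenchyma", "RIDE0004")],
            [],
        ],
    )
    def test_matches_naive_iterate_until_stable(
        self, spec, rules, blank, seed_fields
    ):
        state = blank
        for fid, value in seed_fields:
            state = set_field(state, spec, fid, value)
        assert apply_rules_fixpoint(state, rules, spec) == naive_fixpoint(
            state, rules, spec
        )

    def test_idempotent(self, spec, rules, blank):
        state = set_field(blank, spec, "right_kidney_calculus_count", 1)
        once = apply_rules_fixpoint(state, rules, spec)
        assert apply_rules_fixpoint(once, rules, spec) == once

    def test_implicit_never_overrides_explicit(self, spec, rules, blank):
        state = set_field(blank, spec, "right_kidney_calculus_count", 2)
        state = set_field(state, spec, "right_kidney_status", "RID13173")
        out = apply_rules_fixpoint(state, rules, spec)
        assert out.value_of("right_kidney_status") == "RID13173"

    def test_contradictory_rules_raise_naming_both(self, spec, blank):
        rows = [
            {
                "rule_id": "r_one",
                "kind": "implicit_set",
                "conditions": "filled(right_kidney_calculus_count)",
                "actions": "set(right_kidney_status,RID28453)",
            },
            {
                "rule_id": "r_two",
                "kind": "implicit_set",
                "conditions": "filled(right_kidney_calculus_count)",
                "actions": "set(right_kidney_status,RID13173)",
            },
        ]
        contradictory = load_rules(rows, spec)
        state = set_field(blank, spec, "right_kidney_calculus_count", 1)
        with pytest.raises(RuleError) as err:
            apply_rules_fixpoint(state, contradictory, spec)
        assert "r_one" in str(err.value) and "r_two" in str(err.value)


class TestFilterAdvice:
    @staticmethod
    def make(intent_id, confidence, priority=0):
        return Intent(
            intent_id=intent_id, kind="advice", confidence=confidence,
            priority=priority,
        )

    def test_threshold_zero_keeps_all(self):
        intents = [self.make("a", 0.1), self.make("b", 0.9)]
        assert len(filter_advice(intents, 0.0)) == 2

    def test_threshold_one_keeps_only_certain(self):
        intents = [self.make("a", 0.99), self.make("b", 1.0)]
        assert [i.intent_id for i in filter_advice(intents, 1.0)] == ["b"]

    def test_default_threshold_drops_low_confidence(self):
        intents = [self.make("low", 0.4), self.make("high", 0.9)]
        assert [i.intent_id for i in filter_advice(intents, 0.5)] == ["high"]

    def test_stable_order_priority_then_id(self):
        intents = [
            self.make("b", 1.0, priority=5),
            self.make("a", 1.0, priority=5),
            self.make("c", 1.0, priority=9),
        ]
        assert [i.intent_id for i in filter_advice(intents, 0.0)] == [
            "c", "a", "b",
        ]


class TestProcessTurn:
    def test_worked_example_turn(self, spec, lex, rules, blank):
        result = process_turn(
            blank, "Two calculi in the right kidney.", "right_kidney",
            spec, lex, rules,
        )
        state = result.new_state
        assert state.value_of("right_kidney_status") == "RID28453"
        count = state.values["right_kidney_calculus_count"]
        assert count.value == 2
        assert count.concept_code == "RID4994"
        assert count.verbatim_text.lower() == "two"
        assert any(
            i.slots.get("concept") == "RID34394" for i in result.advice_intents
        )

    def test_no_pathologies_shortcut(self, spec, lex, rules, blank):
        result = process_turn(
            blank, "No pathologies.", "right_kidney", spec, lex, rules
        )
        state = result.new_state
        assert state.value_of("right_kidney_status") == "RID13173"
        assert state.value_of("right_kidney_calculus_count") == 0
        assert state.active_section == "right_ureter"

    def test_statelessness(self, spec, lex, rules, blank):
        text = "Two calculi in the right kidney. The largest measures 7 mm."
        outputs = {
            process_turn(
                blank, text, "right_kidney", spec, lex, rules
            ).model_dump_json()
            for _ in range(25)
        }
        assert len(outputs) == 1

    def test_unknown_focus_rejected(self, spec, lex, rules, blank):
        with pytest.raises(sd.TemplateError):
            process_turn(blank, "hello", "spleen", spec, lex, rules)

    def test_template_confidence_equals_completeness(
        self, spec, lex, rules, blank
    ):
        result = process_turn(
            blank, "Two calculi in the right kidney.", "right_kidney",
            spec, lex, rules,
        )
        conf = result.template_intents[0].confidence
        assert conf == pytest.approx(
            completeness(result.new_state, spec, rules)
        )
        assert result.progress == pytest.approx(conf)

    def test_advice_only_targets_empty_fields(self, spec, lex, rules, blank):
        from srdialog.synthcorpus import GenConfig, generate_report

        cfg = GenConfig(seed=5)
        for i in range(15):
            report = generate_report(cfg, i)
            result = process_turn(
                blank, report.text, "right_kidney", spec, lex, rules
            )
            for intent in result.advice_intents:
                fid = intent.slots.get("field")
                if fid is not None:
                    assert not result.new_state.filled(fid), intent.intent_id

    def test_later_mention_wins_for_same_field(self, spec, lex, rules, blank):
        text = (
            "Two calculi in the right kidney. "
            "Correction: three calculi in the right kidney."
        )
        result = process_turn(
            blank, text, "right_kidney", spec, lex, rules
        )
        assert result.new_state.value_of("right_kidney_calculus_count") == 3

    def test_multi_turn_dialogue_progresses(self, spec, lex, rules, blank):
        state = blank
        turns = [
            "Two calculi in the right kidney.",
            "The largest calculus measures 7 mm with a density of 900 HU.",
            "The calculus is round. It is located in the lower calyx.",
            "No obstructive uropathy. No parenchymal thinning. "
            "No perirenal stranding.",
        ]
        last = 0.0
        for text in turns:
            result = process_turn(
                state, text, "right_kidney", spec, lex, rules
            )
            state = result.new_state
            assert result.progress >= last
            last = result.progress
        from srdialog.template import active_required_fields

        for fid in active_required_fields(state, spec, rules):
            if fid.startswith("right_kidney"):
                assert state.filled(fid), fid
        assert state.active_section == "right_ureter"
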