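"""Task-oriented dialogue management over the structured-report template.

The dialogue manager is stateless: :func:`process_turn` is a pure function of
(state, utterance, resources, config).  A turn runs the pipeline

    extract_structured -> detect_intents -> apply template intents
    -> apply_rules_fixpoint -> filter_advice -> render advice

Template intents fill template fields from affirmed mentions (negated
mentions store the corresponding normal/absent value, speculated mentions are
filled but marked uncertain under the default policy).  The knowledgebase is
a decision table: each row is a rule with predicate conditions over the
template state and the current structured content, and actions that either
derive implicit field values (forward-chained to a fixpoint), activate
conditional fields, emit advice intents, or auto-complete a section when the
user dictates the "no pathologies" shortcut.

Template-intent confidence equals the template's completeness after the turn;
advice-intent confidence is the emitting rule's prior, and intents below the
configured threshold are filtered out.
"""

from __future__ import annotations

import re
from enum import Enum
from typing import Any, Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .config import DEFAULT_CONFIG, EngineConfig
from .extraction import (
    Status,
    StructuredContent,
    TriggerSet,
    Utterance,
    extract_structured,
)
from .lexicon import LexiconIndex
from .template import (
    FillMode,
    TemplateError,
    TemplateSpec,
    TemplateState,
    ValueKind,
    advance_section,
    auto_complete_section,
    completeness,
    set_field,
)


class RuleError(ValueError):
    """Raised for invalid rule documents or contradictory rule sets."""


class RuleKind(str, Enum):
    require_field = "require_field"
    implicit_set = "implicit_set"
    advice = "advice"
    auto_normal = "auto_normal"


_PRED_RE = re.compile(r"^(\w+)\(([^()]*)\)$")


class Predicate(BaseModel):
    model_config = {"frozen": True}

    name: str
    args: tuple[str, ...]

    @classmethod
    def parse(cls, text: str) -> "Predicate":
        m = _PRED_RE.match(text.strip())
        if not m:
            raise RuleError(f"malformed predicate {text!r}")
        name = m.group(1)
        args = tuple(a.strip() for a in m.group(2).split(",") if a.strip())
        arity = {"filled": 1, "not_filled": 1, "has": 2, "num_gt": 2,
                 "mention": 3}
        if name not in arity:
            raise RuleError(f"unknown predicate {name!r}")
        if len(args) != arity[name]:
            raise RuleError(f"{name} expects {arity[name]} args: {text!r}")
        return cls(name=name, args=args)

    def holds(
        self, state: TemplateState, content: Optional[StructuredContent]
    ) -> bool:
        if self.name == "filled":
            return state.filled(self.args[0])
        if self.name == "not_filled":
            return not state.filled(self.args[0])
        if self.name == "has":
            return state.filled(self.args[0]) and state.value_of(
                self.args[0]
            ) == self.args[1]
        if self.name == "num_gt":
            v = state.value_of(self.args[0])
            return isinstance(v, (int, float)) and v > float(self.args[1])
        if self.name == "mention":
            if content is None:
                return False
            code, status, section = self.args
            return any(
                m.code == code and m.status.value == status
                for m in content.mentions.get(section, ())
            )
        raise RuleError(self.name)


class Action(BaseModel):
    model_config = {"frozen": True}

    name: str  # set | require | advise | auto_complete
    args: tuple[str, ...]

    @classmethod
    def parse(cls, text: str) -> "Action":
        m = _PRED_RE.match(text.strip())
        if not m:
            raise RuleError(f"malformed action {text!r}")
        name = m.group(1)
        args = tuple(a.strip() for a in m.group(2).split(",") if a.strip())
        arity = {"set": 2, "require": 1, "advise": 2, "auto_complete": 1}
        if name not in arity:
            raise RuleError(f"unknown action {name!r}")
        if len(args) != arity[name]:
            raise RuleError(f"{name} expects {arity[name]} args: {text!r}")
        return cls(name=name, args=args)


class Rule(BaseModel):
    model_config = {"frozen": True}

    rule_id: str
    kind: RuleKind
    conditions: tuple[Predicate, ...]
    actions: tuple[Action, ...]
    priority: int = 0
    prior: float = Field(default=1.0, ge=0.0, le=1.0)
    description: str = ""

    def conditions_hold(
        self, state: TemplateState, content: Optional[StructuredContent]
    ) -> bool:
        return all(p.holds(state, content) for p in self.conditions)

    @property
    def target_fields(self) -> tuple[str, ...]:
        return tuple(
            a.args[0] for a in self.actions if a.name in ("set", "require")
        )


class Intent(BaseModel):
    model_config = {"frozen": True}

    intent_id: str
    kind: str  # "template" | "advice"
    slots: Mapping[str, Any] = Field(default_factory=dict)
    confidence: float = Field(default=0.0, ge=0.0, le=1.0)
    priority: int = 0
    #: per-slot dictated surface forms (template intents)
    verbatims: Mapping[str, str] = Field(default_factory=dict)
    #: per-slot concept provenance (template intents)
    concepts: Mapping[str, str] = Field(default_factory=dict)
    uncertain_slots: tuple[str, ...] = ()
    flags: Mapping[str, tuple[str, ...]] = Field(default_factory=dict)


class TurnResult(BaseModel):
    model_config = {"frozen": True}

    new_state: TemplateState
    template_intents: tuple[Intent, ...]
    advice_intents: tuple[Intent, ...]
    advice_texts: tuple[str, ...]
    progress: float


# ---------------------------------------------------------------------------
# loading


def load_rules(
    doc: Any, spec: Optional[TemplateSpec] = None
) -> tuple[Rule, ...]:
    """Load a decision table (CSV path, DataFrame, or list of dicts).

    Columns: rule_id, kind, priority, prior, conditions, actions,
    description.  Conditions are predicates joined by " AND "; actions are
    joined by "; ".  With ``spec`` given, every referenced field is checked.
    """
    if isinstance(doc, str):
        doc = pd.read_csv(doc).fillna("")
    if isinstance(doc, pd.DataFrame):
        doc = doc.to_dict("records")
    rules: list[Rule] = []
    for row in doc:
        conditions = tuple(
            Predicate.parse(p)
            for p in str(row["conditions"]).split(" AND ")
            if p.strip()
        )
        actions = tuple(
            Action.parse(a) for a in str(row["actions"]).split(";") if a.strip()
        )
        if not conditions:
            raise RuleError(f"rule {row['rule_id']}: no conditions")
        if not actions:
            raise RuleError(f"rule {row['rule_id']}: no actions")
        rule = Rule(
            rule_id=str(row["rule_id"]),
            kind=RuleKind(row["kind"]),
            conditions=conditions,
            actions=actions,
            priority=int(row.get("priority", 0) or 0),
            prior=float(row.get("prior", 1.0) or 1.0),
            description=str(row.get("description", "")),
        )
        sets = {a.args[0] for a in rule.actions if a.name == "set"}
        requires = {a.args[0] for a in rule.actions if a.name == "require"}
        if sets & requires:
            raise RuleError(
                f"rule {rule.rule_id} both sets and requires {sets & requires}"
            )
        rules.append(rule)
    ids = [r.rule_id for r in rules]
    if len(set(ids)) != len(ids):
        raise RuleError("duplicate rule_id in decision table")
    if spec is not None:
        _validate_references(rules, spec)
    return tuple(rules)


def _validate_references(rules: Sequence[Rule], spec: TemplateSpec) -> None:
    known_fields = set(spec.field_ids)
    known_sections = set(spec.section_ids)
    for rule in rules:
        for pred in rule.conditions:
            if pred.name in ("filled", "not_filled", "has", "num_gt"):
                if pred.args[0] not in known_fields:
                    raise RuleError(
                        f"rule {rule.rule_id}: unknown field {pred.args[0]!r}"
                    )
            elif pred.name == "mention" and pred.args[2] not in known_sections:
                raise RuleError(
                    f"rule {rule.rule_id}: unknown section {pred.args[2]!r}"
                )
        for act in rule.actions:
            if act.name in ("set", "require"):
                if act.args[0] not in known_fields:
                    raise RuleError(
                        f"rule {rule.rule_id}: unknown field {act.args[0]!r}"
                    )
            elif act.name == "advise" and act.args[1] not in known_fields:
                raise RuleError(
                    f"rule {rule.rule_id}: unknown field {act.args[1]!r}"
                )
            elif act.name == "auto_complete" and act.args[0] not in known_sections:
                raise RuleError(
                    f"rule {rule.rule_id}: unknown section {act.args[0]!r}"
                )


def check_advice_coverage(
    rules: Sequence[Rule], mappings: Mapping[str, Any]
) -> None:
    """Every advice rule's intent must have a natural-language mapping."""
    missing = sorted(
        {
            a.args[0]
            for r in rules
            if r.kind is RuleKind.advice
            for a in r.actions
            if a.name == "advise" and a.args[0] not in mappings
        }
    )
    if missing:
        raise RuleError(f"advice intents without NLG mapping: {missing}")


# ---------------------------------------------------------------------------
# intent detection


def _coerce_rule_value(spec: TemplateSpec, field_id: str, raw: str) -> Any:
    field = spec.field(field_id)
    if field.value_kind is ValueKind.count:
        return int(raw)
    if field.value_kind is ValueKind.numeric:
        return float(raw)
    return raw


class _Assignment(BaseModel):
    model_config = {"frozen": True}

    field_id: str
    value: Any
    verbatim: str = ""
    concept_code: Optional[str] = None
    uncertain: bool = False
    flags: tuple[str, ...] = ()
    #: count inferred from a bare singular noun — a fallback that never
    #: overrides an explicitly dictated count
    inferred: bool = False


def _mention_assignments(
    content: StructuredContent,
    spec: TemplateSpec,
    config: EngineConfig,
) -> tuple[list[_Assignment], list[str]]:
    """Field assignments implied by mentions, in dictation order, plus the
    sections to auto-complete ("no pathologies" shortcut)."""
    assignments: list[_Assignment] = []
    auto_sections: list[str] = []
    for section_id, mentions in content.mentions.items():
        if section_id not in spec.section_ids:
            continue
        fields = spec.section_fields(section_id)
        size_field = spec.numeric_field(section_id, "mm")
        density_field = spec.numeric_field(section_id, "HU")
        for mention in mentions:
            if mention.code == "RIDE0005":
                if mention.status is Status.affirmed:
                    auto_sections.append(section_id)
                continue
            for field in fields:
                if mention.code not in field.triggers:
                    continue
                uncertain = False
                if mention.status is Status.speculated:
                    if config.speculation_policy == "ask":
                        continue
                    uncertain = True
                if field.value_kind is ValueKind.count:
                    if mention.status is Status.negated:
                        assignments.append(
                            _Assignment(
                                field_id=field.field_id,
                                value=0,
                                verbatim=mention.verbatim,
                                concept_code=mention.code,
                            )
                        )
                        continue
                    count = mention.count
                    verbatim = mention.count_verbatim
                    inferred = False
                    if count is None and config.infer_singular_count:
                        count, verbatim, inferred = 1, mention.verbatim, True
                    if count is not None:
                        assignments.append(
                            _Assignment(
                                field_id=field.field_id,
                                value=count,
                                verbatim=verbatim,
                                concept_code=mention.code,
                                uncertain=uncertain,
                                inferred=inferred,
                            )
                        )
                    if mention.status is not Status.negated:
                        if size_field and mention.size_mm is not None:
                            assignments.append(
                                _Assignment(
                                    field_id=size_field.field_id,
                                    value=mention.size_mm,
                                    verbatim=mention.verbatim,
                                    concept_code=mention.code,
                                    uncertain=uncertain,
                                    flags=mention.flags,
                                )
                            )
                        if density_field and mention.density_hu is not None:
                            assignments.append(
                                _Assignment(
                                    field_id=density_field.field_id,
                                    value=mention.density_hu,
                                    verbatim=mention.verbatim,
                                    concept_code=mention.code,
                                    uncertain=uncertain,
                                )
                            )
                else:
                    key = (
                        "negated"
                        if mention.status is Status.negated
                        else "affirmed"
                    )
                    stored = field.triggers[mention.code].get(key)
                    if stored is None:
                        continue
                    assignments.append(
                        _Assignment(
                            field_id=field.field_id,
                            value=stored,
                            verbatim=mention.verbatim,
                            concept_code=mention.code,
                            uncertain=uncertain,
                        )
                    )
    # an inferred singular count yields to any dictated count for the field
    explicit_counts = {a.field_id for a in assignments if not a.inferred}
    assignments = [
        a
        for a in assignments
        if not (a.inferred and a.field_id in explicit_counts)
    ]
    return assignments, auto_sections


def _apply_assignments(
    state: TemplateState,
    spec: TemplateSpec,
    assignments: Sequence[_Assignment],
    auto_sections: Sequence[str],
) -> TemplateState:
    for a in assignments:
        if a.inferred and state.filled(a.field_id):
            continue
        state = set_field(
            state,
            spec,
            a.field_id,
            a.value,
            verbatim_text=a.verbatim,
            fill_mode=FillMode.explicit,
            concept_code=a.concept_code,
            uncertain=a.uncertain,
            flags=a.flags,
        )
    for section_id in auto_sections:
        state = auto_complete_section(state, spec, section_id)
    return state


def detect_intents(
    content: StructuredContent,
    state: TemplateState,
    rules: Sequence[Rule],
    spec: TemplateSpec,
    config: EngineConfig = DEFAULT_CONFIG,
) -> list[Intent]:
    """Template and advice intents for one turn (advice unfiltered).

    Template intents are grouped per section; their confidence is the
    completeness of the state after applying every template intent and the
    implicit-completion rules.  Advice intents come from advice rules whose
    conditions all hold on that post-application state.
    """
    assignments, auto_sections = _mention_assignments(content, spec, config)
    post = _apply_assignments(state, spec, assignments, auto_sections)
    post = apply_rules_fixpoint(post, rules, spec)
    conf = completeness(post, spec, rules, config.completeness_mode)

    intents: list[Intent] = []
    by_section: dict[str, list[_Assignment]] = {}
    for a in assignments:
        by_section.setdefault(spec.field(a.field_id).section_id, []).append(a)
    for section_id, assigns in by_section.items():
        slots: dict[str, Any] = {}
        verbatims: dict[str, str] = {}
        concepts: dict[str, str] = {}
        uncertain: list[str] = []
        flags: dict[str, tuple[str, ...]] = {}
        for a in assigns:  # later assignment to the same field wins
            slots[a.field_id] = a.value
            verbatims[a.field_id] = a.verbatim
            if a.concept_code:
                concepts[a.field_id] = a.concept_code
            if a.uncertain and a.field_id not in uncertain:
                uncertain.append(a.field_id)
            if a.flags:
                flags[a.field_id] = a.flags
        intents.append(
            Intent(
                intent_id=f"fill_{section_id}",
                kind="template",
                slots=slots,
                confidence=conf,
                verbatims=verbatims,
                concepts=concepts,
                uncertain_slots=tuple(uncertain),
                flags=flags,
            )
        )
    for section_id in auto_sections:
        intents.append(
            Intent(
                intent_id=f"auto_complete_{section_id}",
                kind="template",
                slots={"section": section_id},
                confidence=conf,
            )
        )
    for rule in rules:
        if rule.kind is not RuleKind.advice:
            continue
        if not rule.conditions_hold(post, content):
            continue
        for act in rule.actions:
            if act.name != "advise":
                continue
            intent_id, field_id = act.args
            field = spec.field(field_id)
            slots: dict[str, Any] = {
                "field": field_id,
                "section": field.section_id,
            }
            if field.triggers:
                slots["concept"] = next(iter(field.triggers))
            intents.append(
                Intent(
                    intent_id=intent_id,
                    kind="advice",
                    slots=slots,
                    confidence=rule.prior,
                    priority=rule.priority,
                )
            )
    return intents


# ---------------------------------------------------------------------------
# forward chaining


def apply_rules_fixpoint(
    state: TemplateState,
    rules: Sequence[Rule],
    spec: TemplateSpec,
) -> TemplateState:
    """Forward-chain implicit_set rules until no rule fires.

    Implicit values never override explicit ones; a field is set at most once
    per fixpoint run, so the chain terminates.  Two rules deriving different
    values for the same field raise :class:`RuleError` naming both.
    """
    implicit_rules = [r for r in rules if r.kind is RuleKind.implicit_set]
    set_by: dict[str, str] = {}
    changed = True
    guard = 0
    while changed:
        guard += 1
        if guard > len(implicit_rules) * len(spec.fields) + 2:
            raise RuleError("implicit rule chain failed to reach a fixpoint")
        changed = False
        for rule in sorted(
            implicit_rules, key=lambda r: (-r.priority, r.rule_id)
        ):
            if not rule.conditions_hold(state, content=None):
                continue
            for act in rule.actions:
                if act.name != "set":
                    continue
                field_id, raw = act.args
                value = _coerce_rule_value(spec, field_id, raw)
                existing = state.values.get(field_id)
                if existing is not None and existing.fill_mode in (
                    FillMode.explicit,
                ):
                    continue
                if (
                    existing is not None
                    and existing.fill_mode is FillMode.implicit
                ):
                    if existing.value == value:
                        continue
                    raise RuleError(
                        "contradictory implicit rules on "
                        f"{field_id!r}: {existing.rule_id} set "
                        f"{existing.value!r}, {rule.rule_id} wants {value!r}"
                    )
                new = set_field(
                    state,
                    spec,
                    field_id,
                    value,
                    fill_mode=FillMode.implicit,
                    rule_id=rule.rule_id,
                )
                if new is not state:
                    state = new
                    set_by[field_id] = rule.rule_id
                    changed = True
    return state


def filter_advice(
    intents: Iterable[Intent], threshold: float
) -> list[Intent]:
    """Keep advice intents at or above the confidence threshold, ordered by
    (priority desc, intent_id)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    kept = [i for i in intents if i.confidence >= threshold]
    return sorted(kept, key=lambda i: (-i.priority, i.intent_id))


# ---------------------------------------------------------------------------
# turns


def process_turn(
    state: TemplateState,
    utterance: Utterance | str,
    focus: Optional[str],
    spec: TemplateSpec,
    lexicon: LexiconIndex,
    rules: Sequence[Rule],
    config: EngineConfig = DEFAULT_CONFIG,
    triggers: Optional[TriggerSet] = None,
    advice_mappings: Optional[Mapping[str, Any]] = None,
) -> TurnResult:
    """Process one dictation turn; stateless and deterministic.

    ``focus`` defaults to the state's active section.  When NLG advice
    mappings are supplied the surviving advice intents are also rendered to
    natural-language questions.
    """
    if isinstance(utterance, str):
        utterance = Utterance(
            text=utterance,
            turn_id=state.turn_counter + 1,
            locale=spec.locale,
        )
    if focus is None:
        focus = state.active_section or spec.section_ids[0]
    if focus not in spec.section_ids:
        raise TemplateError(f"unknown focus section {focus!r}")

    content = extract_structured(utterance, focus, lexicon, triggers, config)
    working = state.model_copy(update={"turn_counter": state.turn_counter + 1})
    intents = detect_intents(content, working, rules, spec, config)
    template_intents = [i for i in intents if i.kind == "template"]
    advice_intents = [i for i in intents if i.kind == "advice"]

    assignments, auto_sections = _mention_assignments(content, spec, config)
    new_state = _apply_assignments(working, spec, assignments, auto_sections)
    new_state = apply_rules_fixpoint(new_state, rules, spec)
    new_state = advance_section(new_state, spec)

    kept = filter_advice(advice_intents, config.advice_threshold)
    texts: list[str] = []
    if advice_mappings is not None:
        from .nlg import render_advice

        texts = [render_advice(i, advice_mappings) for i in kept]
    return TurnResult(
        new_state=new_state,
        template_intents=tuple(template_intents),
        advice_intents=tuple(kept),
        advice_texts=tuple(texts),
        progress=completeness(new_state, spec, rules, config.completeness_mode),
    )
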