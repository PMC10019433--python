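"""Structured-report template model.

A structured-report (SR) template is an ordered collection of sections (organ
systems) holding typed fields: coded fields draw their value from a closed set
of ontology codes, numeric fields carry a unit (mm, HU), count fields hold a
non-negative integer, free-text fields hold arbitrary text.  A report in
progress is a :class:`TemplateState`: an immutable mapping from field ids to
:class:`FieldValue` plus the currently focused section.

Fill modes form a precedence hierarchy — an explicitly dictated value beats a
rule-derived (implicit) one, which beats a section-wide auto-normal default.
``completeness`` is the fraction of *currently required* fields that are
filled; conditional fields (e.g. the size of the largest calculus) only join
the denominator once activated by a ``require_field`` rule (e.g. once a
calculus is documented).  Completeness doubles as the confidence of template
intents in the dialogue layer.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Any, Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

SCHEMA_VERSIONS = {1}


class TemplateError(ValueError):
    """Raised for invalid template documents or inadmissible assignments."""


class ValueKind(str, Enum):
    coded = "coded"
    numeric = "numeric"
    count = "count"
    free_text = "free_text"


class FillMode(str, Enum):
    explicit = "explicit"
    implicit = "implicit"
    auto_normal = "auto_normal"
    empty = "empty"


#: precedence rank; higher rank may overwrite lower, never the other way round
FILL_RANK = {
    FillMode.empty: 0,
    FillMode.auto_normal: 1,
    FillMode.implicit: 2,
    FillMode.explicit: 3,
}


class Requirement(str, Enum):
    always = "always"
    conditional = "conditional"
    never = "never"


class FieldSpec(BaseModel):
    model_config = {"frozen": True}

    field_id: str
    section_id: str
    label: str
    value_kind: ValueKind
    allowed_codes: tuple[str, ...] = ()
    unit: str = ""
    required: Requirement = Requirement.always
    #: id of the require_field rule that activates this conditional field
    required_when: Optional[str] = None
    #: mention handling: concept code -> {"affirmed": stored value or None,
    #: "negated": stored value or None}
    triggers: Mapping[str, Mapping[str, Optional[str]]] = Field(
        default_factory=dict
    )
    #: value written by auto_complete_section (None: left empty)
    normal_value: Optional[Any] = None

    @model_validator(mode="after")
    def _check(self) -> "FieldSpec":
        if self.value_kind is ValueKind.coded and not self.allowed_codes:
            raise TemplateError(
                f"coded field {self.field_id!r} has no allowed_codes"
            )
        if self.value_kind is ValueKind.numeric and not self.unit:
            raise TemplateError(f"numeric field {self.field_id!r} has no unit")
        return self


class TemplateSpec(BaseModel):
    model_config = {"frozen": True}

    template_id: str
    locale: str = "en"
    sections: tuple[tuple[str, str], ...]  # (section_id, label), ordered
    fields: tuple[FieldSpec, ...]

    @model_validator(mode="after")
    def _check(self) -> "TemplateSpec":
        if not self.fields:
            raise TemplateError("template declares zero fields")
        section_ids = [s for s, _ in self.sections]
        if len(set(section_ids)) != len(section_ids):
            raise TemplateError("duplicate section_id")
        seen: set[str] = set()
        for f in self.fields:
            if f.field_id in seen:
                raise TemplateError(f"duplicate field_id {f.field_id!r}")
            seen.add(f.field_id)
            if f.section_id not in section_ids:
                raise TemplateError(
                    f"field {f.field_id!r} references undeclared section "
                    f"{f.section_id!r}"
                )
        return self

    # -- convenience lookups -------------------------------------------------

    def field(self, field_id: str) -> FieldSpec:
        for f in self.fields:
            if f.field_id == field_id:
                return f
        raise TemplateError(f"unknown field {field_id!r}")

    @property
    def field_ids(self) -> tuple[str, ...]:
        return tuple(f.field_id for f in self.fields)

    @property
    def section_ids(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.sections)

    def section_fields(self, section_id: str) -> tuple[FieldSpec, ...]:
        if section_id not in self.section_ids:
            raise TemplateError(f"unknown section {section_id!r}")
        return tuple(f for f in self.fields if f.section_id == section_id)

    def numeric_field(self, section_id: str, unit: str) -> Optional[FieldSpec]:
        """The section's numeric field with the given unit, if any."""
        for f in self.section_fields(section_id):
            if f.value_kind is ValueKind.numeric and f.unit == unit:
                return f
        return None

    def count_field(self, section_id: str) -> Optional[FieldSpec]:
        for f in self.section_fields(section_id):
            if f.value_kind is ValueKind.count:
                return f
        return None


class FieldValue(BaseModel):
    model_config = {"frozen": True}

    field_id: str
    value: Optional[Any] = None
    verbatim_text: str = ""
    fill_mode: FillMode = FillMode.empty
    source_turn: int = 0
    #: ontology code of the concept that produced this value (provenance)
    concept_code: Optional[str] = None
    #: set for speculated statements under the fill_uncertain policy
    uncertain: bool = False
    #: id of the rule that derived an implicit value
    rule_id: Optional[str] = None
    #: provenance flags, e.g. "three_dimensional" for reduced 3-D sizes
    flags: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "FieldValue":
        if (self.fill_mode is FillMode.empty) != (self.value is None):
            raise TemplateError(
                f"field {self.field_id!r}: fill_mode=empty iff value absent"
            )
        if self.fill_mode is FillMode.implicit and self.rule_id is None:
            raise TemplateError(
                f"field {self.field_id!r}: implicit value lacks a rule id"
            )
        return self


class TemplateState(BaseModel):
    model_config = {"frozen": True}

    template_id: str
    values: Mapping[str, FieldValue] = Field(default_factory=dict)
    active_section: str = ""
    turn_counter: int = 0

    @field_validator("values")
    @classmethod
    def _freeze(cls, v: Mapping[str, FieldValue]) -> dict[str, FieldValue]:
        return dict(v)

    def filled(self, field_id: str) -> bool:
        fv = self.values.get(field_id)
        return fv is not None and fv.fill_mode is not FillMode.empty

    def value_of(self, field_id: str) -> Optional[Any]:
        fv = self.values.get(field_id)
        return None if fv is None else fv.value

    def to_json(self) -> str:
        return self.model_dump_json()

    @classmethod
    def from_json(cls, payload: str) -> "TemplateState":
        return cls.model_validate_json(payload)


def empty_state(spec: TemplateSpec) -> TemplateState:
    return TemplateState(
        template_id=spec.template_id,
        values={},
        active_section=spec.section_ids[0],
        turn_counter=0,
    )


# ---------------------------------------------------------------------------
# loading


def load_template(doc: Mapping[str, Any] | str) -> TemplateSpec:
    """Build a validated :class:`TemplateSpec` from a JSON document.

    ``doc`` may be a parsed mapping, a JSON string, or a path to a JSON file.
    """
    if isinstance(doc, str):
        if doc.lstrip().startswith("{"):
            doc = json.loads(doc)
        else:
            with open(doc, "r", encoding="utf-8") as fh:
                doc = json.load(fh)
    version = doc.get("schema_version", 1)
    if version not in SCHEMA_VERSIONS:
        raise TemplateError(f"unsupported schema_version {version!r}")
    from pydantic import ValidationError

    try:
        return TemplateSpec(
            template_id=doc["template_id"],
            locale=doc.get("locale", "en"),
            sections=tuple(
                (s["section_id"], s["label"]) for s in doc["sections"]
            ),
            fields=tuple(FieldSpec(**f) for f in doc["fields"]),
        )
    except ValidationError as err:  # unwrap pydantic's envelope
        raise TemplateError(str(err)) from err


# ---------------------------------------------------------------------------
# completeness


def active_required_fields(
    state: TemplateState,
    spec: TemplateSpec,
    rules: Sequence[Any] = (),
    mode: str = "active",
) -> tuple[str, ...]:
    """Field ids in the current completeness denominator.

    ``mode="all"`` counts every field; ``mode="active"`` counts the
    always-required fields plus the conditional fields whose activating
    ``require_field`` rule currently fires on ``state``.
    """
    if mode == "all":
        return spec.field_ids
    active = [
        f.field_id for f in spec.fields if f.required is Requirement.always
    ]
    activated: set[str] = set()
    for rule in rules:
        if getattr(rule, "kind", None) is not None and rule.kind == "require_field":
            if rule.conditions_hold(state, content=None):
                activated.update(rule.target_fields)
    for f in spec.fields:
        if f.required is Requirement.conditional and f.field_id in activated:
            active.append(f.field_id)
    return tuple(active)


def completeness(
    state: TemplateState,
    spec: TemplateSpec,
    rules: Sequence[Any] = (),
    mode: str = "active",
) -> float:
    """Fraction of currently required fields that are filled, in [0, 1]."""
    for fid in state.values:
        if fid not in spec.field_ids:
            raise TemplateError(f"state references unknown field {fid!r}")
    required = active_required_fields(state, spec, rules, mode)
    if not required:
        return 1.0
    filled = sum(1 for fid in required if state.filled(fid))
    return filled / len(required)


# ---------------------------------------------------------------------------
# assignment


def _admissible(field: FieldSpec, value: Any) -> Any:
    if field.value_kind is ValueKind.coded:
        if value not in field.allowed_codes:
            raise TemplateError(
                f"code {value!r} not admissible for field "
                f"{field.field_id!r} (allowed: {list(field.allowed_codes)})"
            )
        return value
    if field.value_kind is ValueKind.count:
        if not isinstance(value, int) or isinstance(value, bool) or value < 0:
            raise TemplateError(
                f"field {field.field_id!r} expects a non-negative integer "
                f"count, got {value!r}"
            )
        return value
    if field.value_kind is ValueKind.numeric:
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise TemplateError(
                f"field {field.field_id!r} expects a number in "
                f"{field.unit}, got {value!r}"
            )
        return float(value)
    return str(value)


def set_field(
    state: TemplateState,
    spec: TemplateSpec,
    field_id: str,
    value: Any,
    verbatim_text: str = "",
    fill_mode: FillMode = FillMode.explicit,
    *,
    concept_code: Optional[str] = None,
    uncertain: bool = False,
    rule_id: Optional[str] = None,
    flags: Iterable[str] = (),
) -> TemplateState:
    """Return a new state with ``field_id`` assigned.

    Pure: the input state is never modified.  Assignments respect fill-mode
    precedence (explicit > implicit > auto_normal): a lower-precedence write
    onto a higher-precedence value returns the state unchanged.  Re-applying
    an identical assignment is a no-op.
    """
    field = spec.field(field_id)  # raises for unknown field
    value = _admissible(field, value)
    existing = state.values.get(field_id)
    if existing is not None and FILL_RANK[existing.fill_mode] > FILL_RANK[fill_mode]:
        return state
    new_value = FieldValue(
        field_id=field_id,
        value=value,
        verbatim_text=verbatim_text,
        fill_mode=fill_mode,
        source_turn=state.turn_counter,
        concept_code=concept_code,
        uncertain=uncertain,
        rule_id=rule_id,
        flags=tuple(flags),
    )
    if existing == new_value:
        return state
    values = dict(state.values)
    values[field_id] = new_value
    return state.model_copy(update={"values": values})


def auto_complete_section(
    state: TemplateState, spec: TemplateSpec, section_id: str
) -> TemplateState:
    """Fill a section with its normal/absent defaults.

    Every always-required field of the section receives its declared
    ``normal_value`` with fill mode ``auto_normal``; conditional feature
    fields stay empty (they are inactive for a normal organ, so the section's
    completeness contribution is still 1).  The active section advances to the
    next section with unfilled always-required fields.  Idempotent, and never
    overrides explicit or implicit values.
    """
    if section_id not in spec.section_ids:
        raise TemplateError(f"unknown section {section_id!r}")
    new = state
    for f in spec.section_fields(section_id):
        if f.required is Requirement.always and f.normal_value is not None:
            new = set_field(
                new,
                spec,
                f.field_id,
                f.normal_value,
                verbatim_text="",
                fill_mode=FillMode.auto_normal,
            )
    return advance_section(new, spec)


def advance_section(state: TemplateState, spec: TemplateSpec) -> TemplateState:
    """Move active_section to the first section with unfilled always-required
    fields at or after the current one; keep it if every section is done."""
    order = spec.section_ids
    start = order.index(state.active_section) if state.active_section in order else 0
    for sid in order[start:]:  # forward only: reporting is consecutive
        required = [
            f.field_id
            for f in spec.section_fields(sid)
            if f.required is Requirement.always
        ]
        if any(not state.filled(fid) for fid in required):
            if sid != state.active_section:
                return state.model_copy(update={"active_section": sid})
            return state
    return state
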