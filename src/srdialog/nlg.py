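"""Natural-language generation: advice questions and report verbalization.

All wording lives in per-locale YAML data files, never in code, so both
shipped locales can be edited without touching the engine.  Advice mappings
turn an advice intent into a chat-window question; field verbalizations turn
a completed template state into human-readable report lines.
"""

from __future__ import annotations

import string
from typing import Any, Mapping, Sequence

import yaml
from pydantic import BaseModel

from .template import TemplateSpec, TemplateState, ValueKind


class NLGError(ValueError):
    """Raised for unknown intents, unbound variables, missing phrases."""


class AdviceMapping(BaseModel):
    model_config = {"frozen": True}

    intent_id: str
    question_template: str
    locale: str = "en"


class Verbalizations(BaseModel):
    """Field labels and code phrases for one locale."""

    model_config = {"frozen": True}

    locale: str = "en"
    fields: Mapping[str, str]  # field_id -> display phrase
    codes: Mapping[str, str]  # concept code -> display phrase

    def __len__(self) -> int:
        return len(self.fields) + len(self.codes)


def load_advice_mappings(doc: Any) -> dict[str, AdviceMapping]:
    """Load intent-to-question mappings from YAML (path, string, or dict)."""
    doc = _read_yaml(doc)
    locale = doc.get("locale", "en")
    return {
        intent_id: AdviceMapping(
            intent_id=intent_id, question_template=template, locale=locale
        )
        for intent_id, template in doc["mappings"].items()
    }


def load_verbalizations(doc: Any) -> Verbalizations:
    doc = _read_yaml(doc)
    return Verbalizations(
        locale=doc.get("locale", "en"),
        fields=dict(doc["fields"]),
        codes=dict(doc["codes"]),
    )


def _read_yaml(doc: Any) -> dict:
    if isinstance(doc, dict):
        return doc
    if "\n" not in doc:
        with open(doc, "r", encoding="utf-8") as fh:
            doc = fh.read()
    return yaml.safe_load(doc)


def render_advice(intent: Any, mappings: Mapping[str, AdviceMapping]) -> str:
    """Substitute the intent's slots into its question template."""
    mapping = mappings.get(intent.intent_id)
    if mapping is None:
        raise NLGError(f"no advice mapping for intent {intent.intent_id!r}")
    template = mapping.question_template
    needed = {
        name
        for _, name, _, _ in string.Formatter().parse(template)
        if name is not None
    }
    unbound = needed - set(intent.slots)
    if unbound:
        raise NLGError(
            f"intent {intent.intent_id!r}: unbound variables {sorted(unbound)}"
        )
    return template.format(**{k: intent.slots[k] for k in needed})


def render_state(
    state: TemplateState,
    spec: TemplateSpec,
    verbs: Verbalizations,
) -> list[tuple[str, str]]:
    """One (field label, phrase) line per filled field, in template order."""
    lines: list[tuple[str, str]] = []
    for field in spec.fields:
        if not state.filled(field.field_id):
            continue
        label = verbs.fields.get(field.field_id)
        if label is None:
            raise NLGError(f"no verbalization for field {field.field_id!r}")
        value = state.value_of(field.field_id)
        if field.value_kind is ValueKind.coded:
            phrase = verbs.codes.get(value)
            if phrase is None:
                raise NLGError(f"no verbalization for code {value!r}")
        elif field.value_kind is ValueKind.numeric:
            phrase = f"{value:g} {field.unit}".strip()
        elif field.value_kind is ValueKind.count:
            fv = state.values[field.field_id]
            phrase = fv.verbatim_text or str(value)
        else:
            phrase = str(value)
        fv = state.values[field.field_id]
        if fv.uncertain:
            phrase += " (uncertain)"
        lines.append((label, phrase))
    return lines


def check_verbalization_coverage(
    spec: TemplateSpec, verbs: Verbalizations
) -> None:
    """Every template field and every allowed code must have a phrase."""
    missing_fields = [
        f.field_id for f in spec.fields if f.field_id not in verbs.fields
    ]
    missing_codes = sorted(
        {
            code
            for f in spec.fields
            for code in f.allowed_codes
            if code not in verbs.codes
        }
    )
    if missing_fields or missing_codes:
        raise NLGError(
            f"verbalization gaps: fields={missing_fields} codes={missing_codes}"
        )
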