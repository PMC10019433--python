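"""Utterance understanding: segments, concept mentions, status, measurements.

The extractor turns one dictated utterance into :class:`StructuredContent`:

* ``segment_utterance`` splits on sentence punctuation and attributes each
  sentence to an organ section — the section of the last explicit organ
  mention at or before the sentence, falling back to the dialogue focus.
* ``classify_status`` decides affirmed / negated / speculated per mention
  with a deterministic trigger-scope model: negation triggers ("no",
  "without", ...) and speculation triggers ("suspected", "possible", ...)
  project a scope of up to :data:`SCOPE_TOKENS` tokens forward (pre-triggers)
  or backward (post-triggers) within the sentence.  A single in-scope trigger
  allocates 0.9 pseudo-probability to its class and 0.05 to each other class;
  with no trigger the mention is affirmed at 0.9.  When triggers conflict the
  one nearest to the mention wins.  Pseudo-triggers ("no change") block.
* ``extract_measurements`` normalizes sizes to mm (including "a x b x c mm"
  three-dimensional strings, reduced to the largest dimension with a
  provenance flag), densities to HU, and counts from digits or number words.

Everything is a pure function of its inputs; re-running on the same text
gives identical output.
"""

from __future__ import annotations

import re
from enum import Enum
from importlib import resources as _ilres
from typing import Any, Iterable, Mapping, Optional, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

from .config import DEFAULT_CONFIG, EngineConfig
from .lexicon import LexiconIndex, SemanticRole, select_matches, tokenize

SCOPE_TOKENS = 6
_IN_SCOPE = (0.9, 0.05)  # winner / each loser


class Status(str, Enum):
    affirmed = "affirmed"
    negated = "negated"
    speculated = "speculated"


class Utterance(BaseModel):
    model_config = {"frozen": True}

    text: str
    turn_id: int = Field(default=0, ge=0)
    locale: str = "en"


class AttributionMode(str, Enum):
    explicit_mention = "explicit_mention"
    dialogue_focus = "dialogue_focus"


class Segment(BaseModel):
    model_config = {"frozen": True}

    start: int
    end: int
    section_id: str
    attribution_mode: AttributionMode


class MeasurementKind(str, Enum):
    size = "size"
    density = "density"
    count = "count"


class Measurement(BaseModel):
    model_config = {"frozen": True}

    kind: MeasurementKind
    value: float | int
    unit: str  # "mm", "HU", or "" for counts
    start: int
    end: int
    verbatim: str
    flags: tuple[str, ...] = ()


class EntityMention(BaseModel):
    model_config = {"frozen": True}

    code: str
    start: int
    end: int
    status: Status
    status_scores: Mapping[str, float]
    verbatim: str
    count: Optional[int] = None
    count_verbatim: str = ""
    size_mm: Optional[float] = None
    density_hu: Optional[float] = None
    flags: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "EntityMention":
        total = sum(self.status_scores.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"status_scores sum to {total}, expected 1")
        top = max(self.status_scores, key=lambda k: self.status_scores[k])
        if top != self.status.value:
            raise ValueError("status must be the argmax of status_scores")
        if self.size_mm is not None and self.size_mm <= 0:
            raise ValueError("size in mm must be positive")
        if self.count is not None and self.count < 0:
            raise ValueError("count must be non-negative")
        return self


class StructuredContent(BaseModel):
    model_config = {"frozen": True}

    turn_id: int = 0
    #: section_id -> mentions, in reading order
    mentions: Mapping[str, tuple[EntityMention, ...]] = Field(
        default_factory=dict
    )

    @property
    def is_empty(self) -> bool:
        return not any(self.mentions.values())

    def all_mentions(self) -> list[tuple[str, EntityMention]]:
        out = []
        for sec, ms in self.mentions.items():
            out.extend((sec, m) for m in ms)
        return out


# ---------------------------------------------------------------------------
# trigger lexicon


class Trigger(BaseModel):
    model_config = {"frozen": True}

    phrase: str
    kind: Status  # negated or speculated
    position: str  # "pre" (scope forward) or "post" (scope backward)


class TriggerSet(BaseModel):
    model_config = {"frozen": True}

    locale: str
    triggers: tuple[Trigger, ...]
    pseudo: tuple[str, ...] = ()


def load_triggers(doc: Any) -> TriggerSet:
    """Load a trigger set from a YAML path/string or a parsed mapping."""
    if isinstance(doc, TriggerSet):
        return doc
    if isinstance(doc, str):
        if "\n" not in doc:
            with open(doc, "r", encoding="utf-8") as fh:
                doc = fh.read()
        doc = yaml.safe_load(doc)
    triggers = []
    for kind, status in (("negation", Status.negated),
                         ("speculation", Status.speculated)):
        for entry in doc.get(kind, []):
            if isinstance(entry, str):
                entry = {"phrase": entry, "position": "pre"}
            triggers.append(
                Trigger(
                    phrase=entry["phrase"],
                    kind=status,
                    position=entry.get("position", "pre"),
                )
            )
    return TriggerSet(
        locale=doc.get("locale", "en"),
        triggers=tuple(triggers),
        pseudo=tuple(doc.get("pseudo", [])),
    )


def default_triggers(locale: str = "en") -> TriggerSet:
    path = _ilres.files("srdialog.data") / f"triggers_{locale}.yaml"
    return load_triggers(path.read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# number words

NUMBER_WORDS: dict[str, dict[str, int]] = {
    "en": {
        w: i
        for i, w in enumerate(
            "zero one two three four five six seven eight nine ten eleven "
            "twelve thirteen fourteen fifteen sixteen seventeen eighteen "
            "nineteen twenty".split()
        )
    },
    "de": {
        w: i
        for i, w in enumerate(
            "null ein zwei drei vier fünf sechs sieben acht neun zehn elf "
            "zwölf dreizehn vierzehn fünfzehn sechzehn siebzehn achtzehn "
            "neunzehn zwanzig".split()
        )
    },
}
NUMBER_WORDS["de"]["eine"] = 1
NUMBER_WORDS["de"]["einem"] = 1
NUMBER_WORDS["de"]["einer"] = 1


# ---------------------------------------------------------------------------
# segmentation

_SENTENCE_END = re.compile(r"[.!?;]+(?=\s|$)")  # not inside decimals


def _sentence_spans(text: str) -> list[tuple[int, int]]:
    """Sentence spans that tile the text exactly (terminators and trailing
    whitespace belong to the sentence they end)."""
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _SENTENCE_END.finditer(text):
        end = m.end()
        while end < len(text) and text[end].isspace():
            end += 1
        spans.append((start, end))
        start = end
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def segment_utterance(
    utt: Utterance, focus: str, index: LexiconIndex
) -> list[Segment]:
    """Split into sentences and attribute each to an organ section.

    A sentence belongs to the section of the last explicit organ (anatomy)
    mention at or before its end; with no organ mentioned anywhere so far the
    dialogue focus applies.
    """
    spans = _sentence_spans(utt.text)
    tokens = tokenize(utt.text)
    anatomy = [
        m
        for m in select_matches(index.candidates(tokens))
        if index.concept(m.code).semantic_role is SemanticRole.anatomy
        and index.section_of(m.code) is not None
    ]
    segments: list[Segment] = []
    current: Optional[str] = None
    for start, end in spans:
        in_scope = [m for m in anatomy if m.start < end]
        if in_scope:
            current = index.section_of(in_scope[-1].code)
            mode = AttributionMode.explicit_mention
            segments.append(
                Segment(
                    start=start, end=end, section_id=current, attribution_mode=mode
                )
            )
        elif current is not None:
            segments.append(
                Segment(
                    start=start,
                    end=end,
                    section_id=current,
                    attribution_mode=AttributionMode.explicit_mention,
                )
            )
        else:
            segments.append(
                Segment(
                    start=start,
                    end=end,
                    section_id=focus,
                    attribution_mode=AttributionMode.dialogue_focus,
                )
            )
    return segments


# ---------------------------------------------------------------------------
# status classification


def _trigger_occurrences(
    tokens: Sequence[tuple[str, int, int]], triggers: TriggerSet
) -> list[tuple[Trigger, int, int]]:
    """(trigger, first_token_idx, last_token_idx) occurrences, pseudo-blocked."""
    folded = [t.casefold() for t, _, _ in tokens]
    pseudo_keys = [tuple(p.casefold().split()) for p in triggers.pseudo]
    blocked: set[int] = set()
    for key in pseudo_keys:
        n = len(key)
        for i in range(len(folded) - n + 1):
            if tuple(folded[i : i + n]) == key:
                blocked.update(range(i, i + n))
    out = []
    for trig in triggers.triggers:
        key = tuple(trig.phrase.casefold().split())
        n = len(key)
        for i in range(len(folded) - n + 1):
            if tuple(folded[i : i + n]) == key and not any(
                j in blocked for j in range(i, i + n)
            ):
                out.append((trig, i, i + n - 1))
    return out


def classify_status(
    segment_text: str,
    mention_span: tuple[int, int],
    triggers: TriggerSet,
) -> dict[str, float]:
    """Pseudo-probabilities for affirmed / negated / speculated.

    ``mention_span`` is in character offsets relative to ``segment_text``.
    """
    tokens = tokenize(segment_text)
    m_start, m_end = mention_span
    m_tokens = [
        i for i, (_, s, e) in enumerate(tokens) if s < m_end and e > m_start
    ]
    if not m_tokens:
        return _scores(Status.affirmed)
    first, last = m_tokens[0], m_tokens[-1]

    best: Optional[tuple[int, Status]] = None
    for trig, t_first, t_last in _trigger_occurrences(tokens, triggers):
        if t_first in m_tokens or t_last in m_tokens:
            continue  # trigger inside the matched phrase ("no pathologies")
        if trig.position == "pre" and t_last < first:
            distance = first - t_last
        elif trig.position == "post" and t_first > last:
            distance = t_first - last
        else:
            continue
        if distance > SCOPE_TOKENS:
            continue
        if best is None or distance < best[0] or (
            distance == best[0] and trig.kind is Status.negated
        ):
            best = (distance, trig.kind)
    return _scores(best[1] if best else Status.affirmed)


def _scores(winner: Status) -> dict[str, float]:
    hi, lo = _IN_SCOPE
    return {
        s.value: (hi if s is winner else lo)
        for s in (Status.affirmed, Status.negated, Status.speculated)
    }


# ---------------------------------------------------------------------------
# measurements

_NUM = r"(\d+(?:[.,]\d+)?)"
_X = r"\s*[x×]\s*"
_3D_RE = re.compile(
    _NUM + _X + _NUM + _X + _NUM + r"\s*(mm|cm|millimeters?|centimeters?)\b",
    re.IGNORECASE,
)
_SIZE_RE = re.compile(
    _NUM + r"\s*(mm|cm|millimeters?|centimeters?)\b", re.IGNORECASE
)
_DENSITY_RE = re.compile(
    _NUM + r"\s*(HU|hounsfield\s+units?)\b", re.IGNORECASE
)


def _to_float(raw: str) -> float:
    return float(raw.replace(",", "."))


def _to_mm(value: float, unit: str) -> float:
    return value * 10.0 if unit.lower().startswith("c") else value


def extract_measurements(
    segment_text: str,
    locale: str = "en",
    handle_3d_sizes: bool = True,
    exclude: Iterable[tuple[int, int]] = (),
) -> list[Measurement]:
    """Normalized sizes (mm), densities (HU) and counts in reading order.

    Spans in ``exclude`` (e.g. concept mentions such as "grade 2") never
    yield counts.  Malformed numerals are skipped, never raised.  With
    ``handle_3d_sizes`` off, three-dimensional size strings are recognized
    but dropped — emulating templates restricted to one-dimensional sizes.
    """
    taken: list[tuple[int, int]] = list(exclude)
    out: list[Measurement] = []

    def free(start: int, end: int) -> bool:
        return all(end <= s or start >= e for s, e in taken)

    for m in _3D_RE.finditer(segment_text):
        if not free(m.start(), m.end()):
            continue
        taken.append((m.start(), m.end()))
        if not handle_3d_sizes:
            continue
        dims = [_to_mm(_to_float(m.group(i)), m.group(4)) for i in (1, 2, 3)]
        out.append(
            Measurement(
                kind=MeasurementKind.size,
                value=max(dims),
                unit="mm",
                start=m.start(),
                end=m.end(),
                verbatim=m.group(0),
                flags=("three_dimensional",),
            )
        )
    for m in _DENSITY_RE.finditer(segment_text):
        if free(m.start(), m.end()):
            taken.append((m.start(), m.end()))
            out.append(
                Measurement(
                    kind=MeasurementKind.density,
                    value=_to_float(m.group(1)),
                    unit="HU",
                    start=m.start(),
                    end=m.end(),
                    verbatim=m.group(0),
                )
            )
    for m in _SIZE_RE.finditer(segment_text):
        if free(m.start(), m.end()):
            taken.append((m.start(), m.end()))
            out.append(
                Measurement(
                    kind=MeasurementKind.size,
                    value=_to_mm(_to_float(m.group(1)), m.group(2)),
                    unit="mm",
                    start=m.start(),
                    end=m.end(),
                    verbatim=m.group(0),
                )
            )
    words = NUMBER_WORDS.get(locale, NUMBER_WORDS["en"])
    for tok, start, end in tokenize(segment_text):
        if not free(start, end):
            continue
        folded = tok.casefold()
        value: Optional[int] = None
        if folded.isdigit() and len(folded) <= 2:
            value = int(folded)
        elif folded in words:
            value = words[folded]
        if value is not None:
            taken.append((start, end))
            out.append(
                Measurement(
                    kind=MeasurementKind.count,
                    value=value,
                    unit="",
                    start=start,
                    end=end,
                    verbatim=tok,
                )
            )
    return sorted(out, key=lambda m: m.start)


# ---------------------------------------------------------------------------
# composition


def extract_structured(
    utt: Utterance,
    focus: str,
    index: LexiconIndex,
    triggers: Optional[TriggerSet] = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> StructuredContent:
    """Full utterance analysis: segmentation, concepts, status, measurements.

    Measurements attach to the nearest preceding finding mention within the
    same sentence, else the nearest following one; unattached measurements
    are dropped.  Anatomy mentions drive section attribution and are not
    reported as entity mentions.
    """
    if triggers is None:
        triggers = default_triggers(utt.locale)
    segments = segment_utterance(utt, focus, index)
    grouped: dict[str, list[EntityMention]] = {}
    for seg in segments:
        sent = utt.text[seg.start : seg.end]
        tokens = tokenize(sent)
        matches = select_matches(index.candidates(tokens, fuzzy=config.fuzzy_matching))
        concept_matches = [
            m
            for m in matches
            if index.concept(m.code).semantic_role is not SemanticRole.anatomy
        ]
        measurements = extract_measurements(
            sent,
            locale=utt.locale,
            handle_3d_sizes=config.handle_3d_sizes,
            exclude=[(m.start, m.end) for m in matches],
        )
        findings = [
            m
            for m in concept_matches
            if index.concept(m.code).semantic_role is SemanticRole.finding
        ]
        attach: dict[int, dict[str, Any]] = {id(f): {} for f in findings}
        for meas in measurements:
            target = _nearest_finding(findings, meas)
            if target is None:
                continue
            slot = attach[id(target)]
            if meas.kind is MeasurementKind.count and "count" not in slot:
                slot["count"] = int(meas.value)
                slot["count_verbatim"] = meas.verbatim
            elif meas.kind is MeasurementKind.size and "size_mm" not in slot:
                slot["size_mm"] = float(meas.value)
                slot["flags"] = meas.flags
            elif meas.kind is MeasurementKind.density and "density_hu" not in slot:
                slot["density_hu"] = float(meas.value)

        for m in concept_matches:
            scores = classify_status(sent, (m.start, m.end), triggers)
            status = Status(max(scores, key=lambda k: scores[k]))
            payload = attach.get(id(m), {})
            flags = tuple(payload.pop("flags", ()))
            grouped.setdefault(seg.section_id, []).append(
                EntityMention(
                    code=m.code,
                    start=seg.start + m.start,
                    end=seg.start + m.end,
                    status=status,
                    status_scores=scores,
                    verbatim=sent[m.start : m.end],
                    flags=flags,
                    **payload,
                )
            )
    return StructuredContent(
        turn_id=utt.turn_id,
        mentions={k: tuple(v) for k, v in grouped.items()},
    )


def _nearest_finding(findings: list, meas: Measurement):
    preceding = [f for f in findings if f.end <= meas.start]
    if preceding:
        return min(preceding, key=lambda f: meas.start - f.end)
    following = [f for f in findings if f.start >= meas.end]
    if following:
        return min(following, key=lambda f: f.start - meas.end)
    return None
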