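"""Synthetic gold-labeled urolithiasis report generator.

Every other module is testable without clinical data because this module
produces free-text report sentences together with the template state a
correct engine should recover — gold labels hold by construction.  The
phrasing grammar is deliberately a subset of the extractor's competence, so
with all hard-case probabilities at zero the pipeline recovers every gold
state exactly.  Three documented hard cases can be injected at configurable
rates to push reports outside that competence:

* ``distractor_organ`` — a trailing sentence about another, unnamed organ
  ("the contralateral side ...") that a section-attribution model cannot
  place, contaminating the focused organ's fields;
* ``three_d_size`` — a three-dimensional size string ("10 x 8 x 6 mm"),
  which one-dimensional templates cannot hold unless the engine reduces it
  to the largest dimension;
* ``singular_noun`` — a single calculus referred to only as "calculus",
  defeating engines that require an explicit count.

Generation is deterministic given (config, report index).
"""

from __future__ import annotations

import json
import random
from typing import Optional, Sequence

from pydantic import BaseModel, Field, model_validator

from .lexicon import LexiconIndex
from .resources import default_lexicon, urolithiasis_template
from .template import (
    FillMode,
    TemplateSpec,
    TemplateState,
    empty_state,
    set_field,
)

NORMAL = "RID13173"
ABNORMAL = "RID28453"
CALCULUS = "RID4994"
UROPATHY = "RID34394"
ABSENT = "RID28473"
THINNING = "RIDE0004"
STRANDING = "RID50265"
WALLTHICK = "RID50276"
CATHETER = "RID50279"

_MORPH = {
    "RID50231": ["round", "rounded"],
    "RID50233": ["staghorn", "staghorn configuration"],
    "RID50234": ["irregular", "irregularly shaped"],
}
_KLOC = {
    "RID50241": ["upper calyx", "upper pole calyx"],
    "RID50242": ["middle calyx", "mid calyx"],
    "RID50243": ["lower calyx", "lower pole calyx"],
    "RID50244": ["renal pelvis", "pyelon"],
}
_SEG = {
    "RID50271": ["proximal segment", "proximal third"],
    "RID50273": ["distal segment", "distal third"],
    "RIDE0003": ["ureterovesical junction", "UVJ"],
}
_BLOC = {
    "RID50277": ["trigone", "bladder trigone"],
    "RID50278": ["bladder dome"],
}
_GRADE = {
    "RID50251": "grade I",
    "RID50252": "grade II",
    "RID50253": "grade III",
    "RID50254": "grade IV",
}
_WORDS = "zero one two three four five six seven eight nine ten".split()

#: the fields scored in the right-kidney evaluation protocol
RIGHT_KIDNEY_EVAL_FIELDS = (
    "right_kidney_calculus_count",
    "right_kidney_calculus_size",
    "right_kidney_calculus_density",
    "right_kidney_calculus_morphology",
    "right_kidney_calculus_location",
    "right_kidney_obstructive_uropathy",
    "right_kidney_uropathy_grade",
)


class GenConfig(BaseModel):
    model_config = {"frozen": True}

    n_reports: int = Field(default=50, ge=1)
    seed: int = 0
    locale: str = "en"
    p_negation: float = Field(default=0.3, ge=0, le=1)
    p_speculation: float = Field(default=0.1, ge=0, le=1)
    p_distractor_organ: float = Field(default=0.0, ge=0, le=1)
    p_number_word: float = Field(default=0.5, ge=0, le=1)
    p_3d_size: float = Field(default=0.0, ge=0, le=1)
    p_singular_noun: float = Field(default=0.0, ge=0, le=1)
    calculus_count_range: tuple[int, int] = (1, 4)
    size_range_mm: tuple[int, int] = (3, 18)
    density_range_hu: tuple[int, int] = (200, 1400)

    @model_validator(mode="after")
    def _check(self) -> "GenConfig":
        for lo, hi in (
            self.calculus_count_range,
            self.size_range_mm,
            self.density_range_hu,
        ):
            if lo > hi:
                raise ValueError("empty range in generator config")
        return self


class GoldReport(BaseModel):
    model_config = {"frozen": True}

    text: str
    gold: TemplateState
    hard_case_flags: tuple[str, ...] = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "text": self.text,
                "gold": json.loads(self.gold.model_dump_json()),
                "flags": list(self.hard_case_flags),
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "GoldReport":
        doc = json.loads(line)
        return cls(
            text=doc["text"],
            gold=TemplateState.model_validate(doc["gold"]),
            hard_case_flags=tuple(doc.get("flags", [])),
        )


def _rng(cfg: GenConfig, report_index: int) -> random.Random:
    return random.Random((cfg.seed * 1_000_003 + report_index) % (2**31 - 1))


class _Builder:
    """Accumulates sentences and the matching gold assignments."""

    def __init__(self, spec: TemplateSpec):
        self.spec = spec
        self.sentences: list[str] = []
        self.gold = empty_state(spec)
        self.flags: list[str] = []

    def say(self, sentence: str) -> None:
        self.sentences.append(sentence)

    def set(self, field_id: str, value, verbatim: str = "") -> None:
        if field_id in self.spec.field_ids:
            self.gold = set_field(
                self.gold, self.spec, field_id, value, verbatim
            )

    def report(self) -> GoldReport:
        return GoldReport(
            text=" ".join(self.sentences),
            gold=self.gold,
            hard_case_flags=tuple(dict.fromkeys(self.flags)),
        )


def _count_phrase(n: int, rng: random.Random, cfg: GenConfig) -> str:
    if rng.random() < cfg.p_number_word and n < len(_WORDS):
        return _WORDS[n]
    return str(n)


def _size_phrase(
    s: int, rng: random.Random, cfg: GenConfig, b: "_Builder"
) -> str:
    if rng.random() < cfg.p_3d_size:
        dims = [s, max(1, s - rng.randint(1, 3)), max(1, s - rng.randint(1, 4))]
        rng.shuffle(dims)
        b.flags.append("three_d_size")
        return " × ".join(str(d) for d in dims) + " mm"
    if s % 10 != 0 and rng.random() < 0.3:
        return f"{s / 10:.1f} cm"
    return f"{s} mm"


def _calculus_block(
    b: "_Builder",
    sec: str,
    organ: str,
    rng: random.Random,
    cfg: GenConfig,
    name_organ: bool = True,
) -> None:
    """Sentences documenting >= 1 calculus with its features."""
    n = rng.randint(*cfg.calculus_count_range)
    singular = rng.random() < cfg.p_singular_noun
    if singular:
        n = 1
        b.flags.append("singular_noun")
        opening = rng.choice(
            [f"Calculus in the {organ}.", f"Solitary calculus in the {organ}."]
        ) if name_organ else "Solitary calculus."
        count_verbatim = "calculus"
    else:
        cnt = _count_phrase(n, rng, cfg)
        noun = "calculus" if n == 1 else rng.choice(["calculi", "stones"])
        if name_organ:
            opening = rng.choice(
                [
                    f"The {organ} shows {cnt} {noun}.",
                    f"{cnt.capitalize()} {noun} in the {organ}.",
                ]
            )
        else:
            opening = f"{cnt.capitalize()} {noun}."
        count_verbatim = cnt
    b.say(opening)
    b.set(f"{sec}_calculus_count", n, count_verbatim)
    b.set(f"{sec}_status", ABNORMAL)

    s = rng.randint(*cfg.size_range_mm)
    size_text = _size_phrase(s, rng, cfg, b)
    b.say(
        rng.choice(
            [
                f"The largest calculus measures {size_text}.",
                f"Largest calculus: {size_text}.",
            ]
        )
    )
    b.set(f"{sec}_calculus_size", float(s), size_text)

    d = rng.randint(*cfg.density_range_hu)
    b.say(
        rng.choice(
            [
                f"The calculus shows a density of {d} HU.",
                f"Density of the calculus: {d} HU.",
            ]
        )
    )
    b.set(f"{sec}_calculus_density", float(d), f"{d} HU")

    if f"{sec}_calculus_morphology" in b.spec.field_ids:
        code = rng.choice(sorted(_MORPH))
        b.say(f"The calculus is {rng.choice(_MORPH[code])}.")
        b.set(f"{sec}_calculus_morphology", code)
    if f"{sec}_calculus_location" in b.spec.field_ids:
        table = _KLOC if sec.endswith("kidney") else _BLOC
        code = rng.choice(sorted(table))
        b.say(f"It is located in the {rng.choice(table[code])}.")
        b.set(f"{sec}_calculus_location", code)
    if f"{sec}_segment_location" in b.spec.field_ids:
        code = rng.choice(sorted(_SEG))
        b.say(f"It is located in the {rng.choice(_SEG[code])}.")
        b.set(f"{sec}_segment_location", code)


def _uropathy_block(
    b: "_Builder", sec: str, rng: random.Random, cfg: GenConfig
) -> None:
    fid = f"{sec}_obstructive_uropathy"
    if rng.random() < 0.5:
        if rng.random() < cfg.p_speculation:
            b.say("Suspected obstructive uropathy.")
            b.set(fid, UROPATHY, "suspected")
        else:
            grade = rng.choice(sorted(_GRADE))
            b.say(
                rng.choice(
                    [
                        f"There is obstructive uropathy, {_GRADE[grade]}.",
                        f"Obstructive uropathy {_GRADE[grade]} is present.",
                    ]
                )
            )
            b.set(fid, UROPATHY)
            if f"{sec}_uropathy_grade" in b.spec.field_ids:
                b.set(f"{sec}_uropathy_grade", grade)
    else:
        b.say(
            rng.choice(
                ["No obstructive uropathy.", "Without obstructive uropathy."]
            )
        )
        b.set(fid, ABSENT)


def _distractor(b: "_Builder", rng: random.Random, n: int, s: int) -> None:
    b.say(
        f"The contralateral side shows {n} calculi, "
        f"the largest measuring {s} mm."
    )
    b.flags.append("distractor_organ")


def generate_right_kidney_report(
    cfg: GenConfig, report_index: int, spec: Optional[TemplateSpec] = None
) -> GoldReport:
    """One report with >= 1 right-kidney calculus, gold over the 7 evaluated
    fields (count, size, density, morphology, location, uropathy, grade)."""
    spec = spec or urolithiasis_template()
    rng = _rng(cfg, report_index)
    b = _Builder(spec)
    _calculus_block(b, "right_kidney", "right kidney", rng, cfg)
    _uropathy_block(b, "right_kidney", rng, cfg)
    # restrict gold to the evaluation protocol's field set
    values = {
        fid: fv
        for fid, fv in b.gold.values.items()
        if fid in RIGHT_KIDNEY_EVAL_FIELDS
    }
    b.gold = b.gold.model_copy(update={"values": values})
    if rng.random() < cfg.p_distractor_organ:
        n = b.gold.value_of("right_kidney_calculus_count") + 1
        s = int(b.gold.value_of("right_kidney_calculus_size") or 5) + 3
        _distractor(b, rng, n, s)
    return b.report()


def generate_report(
    cfg: GenConfig, report_index: int, spec: Optional[TemplateSpec] = None
) -> GoldReport:
    """One multi-organ report with full gold for the sections it covers."""
    spec = spec or urolithiasis_template()
    rng = _rng(cfg, report_index)
    b = _Builder(spec)
    sections = [
        (sec, label) for sec, label in spec.sections
    ]
    chosen = [sl for sl in sections if rng.random() < 0.6]
    if not chosen:
        chosen = [sections[rng.randrange(len(sections))]]
    for sec, organ in chosen:
        if rng.random() < 0.2:
            b.say(f"No pathologies in the {organ}.")
            for field in spec.section_fields(sec):
                if field.required == "always" and field.normal_value is not None:
                    b.set(field.field_id, field.normal_value)
            continue
        has_calc = rng.random() < 0.7
        if has_calc:
            _calculus_block(b, sec, organ, rng, cfg)
        else:
            b.say(
                rng.choice(
                    [
                        f"No calculi in the {organ}.",
                        f"The {organ} is free of calculi.",
                    ]
                )
            )
            b.set(f"{sec}_calculus_count", 0)
        if f"{sec}_obstructive_uropathy" in spec.field_ids:
            _uropathy_block(b, sec, rng, cfg)
            if b.gold.value_of(f"{sec}_obstructive_uropathy") == UROPATHY:
                b.set(f"{sec}_status", ABNORMAL)
        if f"{sec}_parenchyma" in spec.field_ids:
            if rng.random() < 0.25:
                b.say("There is parenchymal thinning.")
                b.set(f"{sec}_parenchyma", THINNING)
                b.set(f"{sec}_status", ABNORMAL)
            else:
                b.say("No parenchymal thinning.")
                b.set(f"{sec}_parenchyma", NORMAL)
        if f"{sec}_perirenal_space" in spec.field_ids:
            if rng.random() < 0.25:
                b.say("There is perirenal fat stranding.")
                b.set(f"{sec}_perirenal_space", STRANDING)
                b.set(f"{sec}_status", ABNORMAL)
            elif rng.random() < cfg.p_negation:
                b.say("No perirenal stranding.")
                b.set(f"{sec}_perirenal_space", NORMAL)
            else:
                b.say("Perirenal space unremarkable.")
                b.set(f"{sec}_perirenal_space", NORMAL)
        if f"{sec}_wall" in spec.field_ids:
            if rng.random() < 0.2:
                b.say("There is wall thickening.")
                b.set(f"{sec}_wall", WALLTHICK)
                b.set(f"{sec}_status", ABNORMAL)
            else:
                b.say("No wall thickening.")
                b.set(f"{sec}_wall", NORMAL)
        if f"{sec}_other_findings" in spec.field_ids and rng.random() < 0.15:
            b.say("Foley catheter in place.")
            b.set(f"{sec}_other_findings", CATHETER)
            b.set(f"{sec}_status", ABNORMAL)
        if has_calc and sec.endswith("kidney") and (
            rng.random() < cfg.p_distractor_organ
        ):
            n = (b.gold.value_of(f"{sec}_calculus_count") or 0) + 1
            s = int(b.gold.value_of(f"{sec}_calculus_size") or 5) + 3
            _distractor(b, rng, n, s)
    return b.report()


def generate_corpus(
    cfg: GenConfig, spec: Optional[TemplateSpec] = None
) -> list[GoldReport]:
    return [generate_report(cfg, i, spec) for i in range(cfg.n_reports)]


def generate_right_kidney_eval(
    cfg: GenConfig, n: int = 50, spec: Optional[TemplateSpec] = None
) -> list[GoldReport]:
    """The right-kidney evaluation corpus: n reports, 7 gold slots each."""
    return [generate_right_kidney_report(cfg, i, spec) for i in range(n)]


# ---------------------------------------------------------------------------
# field-coverage suite


def _coverage_sentences(
    spec: TemplateSpec, field, organ: str, variant: int
) -> tuple[str, list[tuple[str, object, str]]]:
    """(sentence, gold assignments) exercising one field, two phrasings."""
    sec = field.section_id
    fid = field.field_id
    abn = [(f"{sec}_status", ABNORMAL, "")]
    name = fid[len(sec) + 1 :]
    if name == "status":
        return (
            [f"The {organ} is unremarkable.", f"The {organ} is abnormal."][variant],
            [(fid, [NORMAL, ABNORMAL][variant], "")],
        )
    if name == "calculus_count":
        return (
            [
                f"The {organ} shows two calculi.",
                f"Three calculi in the {organ}.",
            ][variant],
            [(fid, [2, 3][variant], ["two", "Three"][variant])] + abn,
        )
    if name == "calculus_size":
        return (
            [
                f"The {organ} shows one calculus measuring 7 mm.",
                f"One calculus of 9 mm in the {organ}.",
            ][variant],
            [
                (fid, [7.0, 9.0][variant], ""),
                (f"{sec}_calculus_count", 1, ""),
            ]
            + abn,
        )
    if name == "calculus_density":
        return (
            [
                f"The {organ} shows one calculus with a density of 900 HU.",
                f"One calculus of 850 HU in the {organ}.",
            ][variant],
            [
                (fid, [900.0, 850.0][variant], ""),
                (f"{sec}_calculus_count", 1, ""),
            ]
            + abn,
        )
    if name == "calculus_morphology":
        code = ["RID50231", "RID50233"][variant]
        word = ["round", "staghorn"][variant]
        return (
            [
                f"The {organ} shows one {word} calculus.",
                f"One {word} calculus in the {organ}.",
            ][variant],
            [(fid, code, ""), (f"{sec}_calculus_count", 1, "")] + abn,
        )
    if name == "calculus_location":
        table = _KLOC if sec.endswith("kidney") else _BLOC
        codes = sorted(table)
        code = codes[variant % len(codes)]
        phrase = table[code][0]
        return (
            [
                f"The {organ} shows one calculus in the {phrase}.",
                f"One calculus at the {phrase} of the {organ}.",
            ][variant],
            [(fid, code, ""), (f"{sec}_calculus_count", 1, "")] + abn,
        )
    if name == "segment_location":
        code = ["RID50273", "RIDE0003"][variant]
        phrase = _SEG[code][0]
        return (
            [
                f"The {organ} shows one calculus in the {phrase}.",
                f"One calculus at the {phrase} of the {organ}.",
            ][variant],
            [(fid, code, ""), (f"{sec}_calculus_count", 1, "")] + abn,
        )
    if name == "obstructive_uropathy":
        if variant == 0:
            return (
                f"There is obstructive uropathy of the {organ}.",
                [(fid, UROPATHY, "")] + abn,
            )
        return (
            f"No obstructive uropathy of the {organ}.",
            [(fid, ABSENT, "")],
        )
    if name == "uropathy_grade":
        code = ["RID50252", "RID50253"][variant]
        phrase = _GRADE[code]
        return (
            [
                f"Obstructive uropathy {phrase} of the {organ}.",
                f"The {organ} shows {phrase} obstructive uropathy.",
            ][variant],
            [(fid, code, ""), (f"{sec}_obstructive_uropathy", UROPATHY, "")]
            + abn,
        )
    if name == "parenchyma":
        if variant == 0:
            return (
                f"Parenchymal thinning of the {organ}.",
                [(fid, THINNING, "")] + abn,
            )
        return (
            f"The {organ} shows no parenchymal thinning.",
            [(fid, NORMAL, "")],
        )
    if name == "perirenal_space":
        if variant == 0:
            return (
                f"Perirenal fat stranding at the {organ}.",
                [(fid, STRANDING, "")] + abn,
            )
        return (
            f"The {organ}: perirenal space unremarkable.",
            [(fid, NORMAL, "")],
        )
    if name == "wall":
        if variant == 0:
            return (
                f"Wall thickening of the {organ}.",
                [(fid, WALLTHICK, "")] + abn,
            )
        return (f"The {organ} shows no wall thickening.", [(fid, NORMAL, "")])
    if name == "other_findings":
        return (
            [
                f"Foley catheter in the {organ}.",
                f"The {organ} shows a bladder catheter.",
            ][variant],
            [(fid, CATHETER, "")] + abn,
        )
    # generic fallback for toy templates: coded fields with triggers
    if field.triggers:
        code = next(iter(field.triggers))
        stored = field.triggers[code].get("affirmed")
        lex: LexiconIndex = default_lexicon()
        syns = lex.concept(code).synonyms if code in lex else (code,)
        syn = syns[min(variant, len(syns) - 1)]
        return (f"The {organ} shows {syn}.", [(fid, stored, syn)])
    raise ValueError(f"no coverage phrasing for field {fid!r}")


def generate_field_coverage_suite(
    spec: Optional[TemplateSpec] = None, cfg: Optional[GenConfig] = None
) -> list[GoldReport]:
    """Two single-field reports per template field, distinct phrasings."""
    spec = spec or urolithiasis_template()
    labels = dict(spec.sections)
    reports: list[GoldReport] = []
    for field in spec.fields:
        for variant in (0, 1):
            b = _Builder(spec)
            sentence, assignments = _coverage_sentences(
                spec, field, labels[field.section_id], variant
            )
            b.say(sentence)
            for fid, value, verbatim in assignments:
                if value is not None:
                    b.set(fid, value, verbatim)
            reports.append(b.report())
    return reports


def write_jsonl(reports: Sequence[GoldReport], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(r.to_json() + "\n")


def read_jsonl(path: str) -> list[GoldReport]:
    with open(path, "r", encoding="utf-8") as fh:
        return [GoldReport.from_json(line) for line in fh if line.strip()]
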