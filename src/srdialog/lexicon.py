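"""Concept lexicon: an ontology subset with synonyms, and phrase matching.

The lexicon holds the RadLex concepts the structured-report template needs
(codes ``RID<digits>``) plus locally minted extensions (``RIDE<digits>``) for
terms absent from the ontology.  Matching is dictionary-based: case-folded,
token-boundary-aligned, longest-match-wins.  Morphological variants
(calculus/calculi) are listed as synonyms rather than stemmed, which keeps the
matcher deterministic and locale-portable.

An optional edit-distance-1 mode (off by default) tolerates single-character
dictation typos in individual tokens; it changes candidate *token* equality
only, the span/selection semantics are identical.
"""

from __future__ import annotations

import re
from enum import Enum
from typing import Any, Iterable, Mapping, Optional

import yaml
from pydantic import BaseModel, model_validator

_CODE_RE = re.compile(r"^RIDE?\d+$")
_TOKEN_RE = re.compile(r"\w+", re.UNICODE)


class LexiconError(ValueError):
    """Raised for invalid lexicon documents."""


class SemanticRole(str, Enum):
    finding = "finding"
    anatomy = "anatomy"
    morphology = "morphology"
    location = "location"
    modifier = "modifier"
    grade = "grade"


class Concept(BaseModel):
    model_config = {"frozen": True}

    code: str
    preferred_label: str
    synonyms: tuple[str, ...]
    locale: str = "en"
    semantic_role: SemanticRole = SemanticRole.modifier
    #: for anatomy concepts: the template section this organ maps to
    section_id: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "Concept":
        if not _CODE_RE.match(self.code):
            raise LexiconError(f"malformed concept code {self.code!r}")
        if not self.preferred_label:
            raise LexiconError(f"{self.code}: empty preferred_label")
        if not self.synonyms:
            raise LexiconError(f"{self.code}: no synonyms")
        return self

    @property
    def is_extension(self) -> bool:
        """True for locally minted RIDE codes (not part of the ontology)."""
        return self.code.startswith("RIDE")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Word tokens with 0-based half-open character spans."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def _token_key(phrase: str) -> tuple[str, ...]:
    return tuple(t.casefold() for t, _, _ in tokenize(phrase))


class Match(BaseModel):
    model_config = {"frozen": True}

    code: str
    start: int
    end: int
    text: str
    n_tokens: int


class LexiconIndex:
    """Exact-phrase index over case-folded synonym token sequences."""

    def __init__(self, concepts: Iterable[Concept]):
        self.concepts: dict[str, Concept] = {}
        #: token-sequence -> code
        self._phrases: dict[tuple[str, ...], str] = {}
        for c in concepts:
            if c.code in self.concepts:
                raise LexiconError(f"duplicate concept code {c.code}")
            self.concepts[c.code] = c
            for syn in c.synonyms:
                key = _token_key(syn)
                if not key:
                    raise LexiconError(f"{c.code}: empty synonym {syn!r}")
                owner = self._phrases.get(key)
                if owner is not None and owner != c.code:
                    raise LexiconError(
                        f"synonym {syn!r} is ambiguous between {owner} "
                        f"and {c.code}"
                    )
                self._phrases[key] = c.code
        self._max_len = max((len(k) for k in self._phrases), default=0)

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, code: str) -> bool:
        return code in self.concepts

    def concept(self, code: str) -> Concept:
        try:
            return self.concepts[code]
        except KeyError:
            raise LexiconError(f"unknown concept code {code!r}") from None

    @property
    def extensions(self) -> tuple[Concept, ...]:
        return tuple(c for c in self.concepts.values() if c.is_extension)

    def section_of(self, code: str) -> Optional[str]:
        c = self.concepts.get(code)
        return c.section_id if c is not None else None

    # -- matching ------------------------------------------------------------

    def candidates(
        self, tokens: list[tuple[str, int, int]], fuzzy: bool = False
    ) -> list[Match]:
        """All synonym occurrences over the token sequence (may overlap)."""
        folded = [t.casefold() for t, _, _ in tokens]
        out: list[Match] = []
        for i in range(len(tokens)):
            for length in range(1, min(self._max_len, len(tokens) - i) + 1):
                window = tuple(folded[i : i + length])
                code = self._phrases.get(window)
                if code is None and fuzzy:
                    code = self._fuzzy_lookup(window)
                if code is not None:
                    start = tokens[i][1]
                    end = tokens[i + length - 1][2]
                    out.append(
                        Match(
                            code=code,
                            start=start,
                            end=end,
                            text="",
                            n_tokens=length,
                        )
                    )
        return out

    def _fuzzy_lookup(self, window: tuple[str, ...]) -> Optional[str]:
        import edlib

        for key, code in self._phrases.items():
            if len(key) != len(window):
                continue
            if all(
                a == b
                or edlib.align(a, b, task="distance", k=1)["editDistance"] == 1
                for a, b in zip(window, key)
            ):
                return code
        return None


def select_matches(candidates: list[Match]) -> list[Match]:
    """Resolve overlaps: keep the longest match, ties to the earlier start."""
    ordered = sorted(
        candidates,
        key=lambda m: (-m.n_tokens, -(m.end - m.start), m.start, m.code),
    )
    chosen: list[Match] = []
    for cand in ordered:
        if all(cand.end <= c.start or cand.start >= c.end for c in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda m: m.start)


def match_concepts(
    text: str, index: LexiconIndex, fuzzy: bool = False
) -> list[tuple[str, tuple[int, int]]]:
    """Concept occurrences in ``text`` as (code, (start, end)) pairs.

    Case-insensitive, token-boundary-aligned; overlapping candidates are
    resolved longest-first (ties: earlier start).  Spans are 0-based half-open
    character offsets into the input.
    """
    tokens = tokenize(text)
    chosen = select_matches(index.candidates(tokens, fuzzy=fuzzy))
    return [(m.code, (m.start, m.end)) for m in chosen]


# ---------------------------------------------------------------------------
# loading


def load_lexicon(doc: Any) -> LexiconIndex:
    """Load a lexicon from a YAML/CSV file path, a YAML string, or a list.

    YAML layout: a list of mappings with keys ``code``, ``preferred_label``,
    ``locale``, ``semantic_role``, ``synonyms`` (list), optional
    ``section_id``.  CSV columns are the same with ``synonyms``
    pipe-separated.
    """
    if isinstance(doc, LexiconIndex):
        return doc
    if isinstance(doc, str):
        if "\n" not in doc and doc.endswith(".csv"):
            import pandas as pd

            frame = pd.read_csv(doc).fillna("")
            entries = [
                {
                    **row,
                    "synonyms": [
                        s.strip() for s in str(row["synonyms"]).split("|") if s.strip()
                    ],
                    "section_id": row.get("section_id") or None,
                }
                for row in frame.to_dict("records")
            ]
        else:
            if "\n" not in doc:
                with open(doc, "r", encoding="utf-8") as fh:
                    doc = fh.read()
            entries = yaml.safe_load(doc) or []
    else:
        entries = list(doc)
    from pydantic import ValidationError

    try:
        concepts = [
            e if isinstance(e, Concept) else Concept(**e) for e in entries
        ]
    except ValidationError as err:
        raise LexiconError(str(err)) from err
    return LexiconIndex(concepts)


def check_template_coverage(index: LexiconIndex, spec: Any) -> None:
    """Every allowed or trigger code in the template must be a known concept."""
    missing = []
    for f in spec.fields:
        for code in list(f.allowed_codes) + list(f.triggers):
            if code not in index:
                missing.append((f.field_id, code))
    if missing:
        raise LexiconError(f"template codes missing from lexicon: {missing}")
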