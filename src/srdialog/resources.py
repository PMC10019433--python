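"""Access to the shipped urolithiasis knowledgebase and locale data."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources as _ilres

from .dialogue import Rule, load_rules
from .extraction import TriggerSet, load_triggers
from .lexicon import LexiconIndex, load_lexicon
from .nlg import (
    AdviceMapping,
    Verbalizations,
    load_advice_mappings,
    load_verbalizations,
)
from .template import TemplateSpec, load_template


def _read(name: str) -> str:
    return (_ilres.files("srdialog.data") / name).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def urolithiasis_template() -> TemplateSpec:
    return load_template(_read("template_urolithiasis_en.json"))


@lru_cache(maxsize=None)
def default_lexicon(locale: str = "en") -> LexiconIndex:
    return load_lexicon(_read(f"lexicon_{locale}.yaml"))


@lru_cache(maxsize=None)
def default_rules() -> tuple[Rule, ...]:
    import io

    import pandas as pd

    frame = pd.read_csv(io.StringIO(_read("rules_urolithiasis.csv"))).fillna("")
    return load_rules(frame, urolithiasis_template())


@lru_cache(maxsize=None)
def default_trigger_set(locale: str = "en") -> TriggerSet:
    return load_triggers(_read(f"triggers_{locale}.yaml"))


@lru_cache(maxsize=None)
def default_advice_mappings(locale: str = "en") -> dict[str, AdviceMapping]:
    return load_advice_mappings(_read(f"nlg_advice_{locale}.yaml"))


@lru_cache(maxsize=None)
def default_verbalizations(locale: str = "en") -> Verbalizations:
    return load_verbalizations(_read(f"nlg_fields_{locale}.yaml"))
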