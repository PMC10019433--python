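"""Engine configuration.

All behavioural switches of the pipeline live here so that a turn is a pure
function of (state, utterance, resources, config).  Two of the switches exist
specifically to emulate known failure modes of naive report extractors:
``handle_3d_sizes`` (off: three-dimensional size strings are dropped instead of
reduced to their largest dimension) and ``infer_singular_count`` (off: a bare
singular finding noun no longer implies a count of one).
"""

from __future__ import annotations

from typing import Literal

import yaml
from pydantic import BaseModel, Field


class EngineConfig(BaseModel):
    """Switches governing extraction, dialogue and scoring behaviour."""

    model_config = {"frozen": True}

    locale: str = "en"
    #: reduce "a x b x c mm" to max(a, b, c); off drops such sizes entirely
    handle_3d_sizes: bool = True
    #: a bare singular finding noun ("calculus") implies count = 1
    infer_singular_count: bool = True
    #: keep advice intents with confidence >= this threshold
    advice_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    #: how speculated findings are handled: fill the field but mark it
    #: uncertain, or leave it empty and ask the user
    speculation_policy: Literal["fill_uncertain", "ask"] = "fill_uncertain"
    #: completeness denominator: only currently-required fields, or all fields
    completeness_mode: Literal["active", "all"] = "active"
    #: scoring convention for a wrong predicted value
    wrong_value_policy: Literal["fp_and_fn", "fp_only"] = "fp_and_fn"
    #: optional edit-distance-1 lexicon matching for dictation typos
    fuzzy_matching: bool = False


def load_config(path: str) -> EngineConfig:
    """Read an :class:`EngineConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return EngineConfig(**doc)


DEFAULT_CONFIG = EngineConfig()
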