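"""Field-value scoring: precision, recall and F1 against gold states.

A predicted and a gold template state are compared field by field.  A filled
field matching the gold value (numeric equality, exact codes, integer counts,
case-folded text) is a true positive; a predicted value where gold is empty
is a false positive; a missed gold value is a false negative; a *wrong*
predicted value is counted as both a false positive and a false negative
under the default strict policy (configurable to FP only).  Counts are pooled
over all reports and fields (micro-averaging) before computing

    P = TP / (TP + FP),   R = TP / (TP + FN),   F1 = 2PR / (P + R).

When there is nothing to find and nothing claimed (all denominators zero) the
metrics are defined as 1.0; a single zero denominator gives 0.0 for that
metric.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .config import DEFAULT_CONFIG, EngineConfig
from .dialogue import Rule, process_turn
from .lexicon import LexiconIndex
from .extraction import TriggerSet
from .template import TemplateSpec, TemplateState, ValueKind, empty_state


class EvalCounts(BaseModel):
    tp: int = Field(default=0, ge=0)
    fp: int = Field(default=0, ge=0)
    fn: int = Field(default=0, ge=0)
    per_field: dict[str, tuple[int, int, int]] = Field(default_factory=dict)

    def add(self, other: "EvalCounts") -> "EvalCounts":
        per_field = dict(self.per_field)
        for fid, (tp, fp, fn) in other.per_field.items():
            a, b, c = per_field.get(fid, (0, 0, 0))
            per_field[fid] = (a + tp, b + fp, c + fn)
        return EvalCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            per_field=per_field,
        )


class EvalMetrics(BaseModel):
    model_config = {"frozen": True}

    precision: float
    recall: float
    f1: float


class ErrorRecord(BaseModel):
    model_config = {"frozen": True}

    report_index: int
    field_id: str
    error_type: str  # "fp" | "fn"
    predicted: Optional[str]
    gold: Optional[str]
    hard_case_flags: tuple[str, ...] = ()


class EvalResult(BaseModel):
    model_config = {"frozen": True, "arbitrary_types_allowed": True}

    metrics: EvalMetrics
    counts: EvalCounts
    per_field: pd.DataFrame
    errors: tuple[ErrorRecord, ...]


def _normalize(spec: TemplateSpec, field_id: str, value):
    kind = spec.field(field_id).value_kind
    if value is None:
        return None
    if kind is ValueKind.numeric:
        return float(value)
    if kind is ValueKind.count:
        return int(value)
    if kind is ValueKind.free_text:
        return str(value).casefold().strip()
    return str(value)


def compare_states(
    predicted: TemplateState,
    gold: TemplateState,
    fields: Sequence[str],
    spec: TemplateSpec,
    wrong_value_policy: str = "fp_and_fn",
) -> EvalCounts:
    """Per-field TP/FP/FN tallies for one report."""
    if predicted.template_id != gold.template_id:
        raise ValueError(
            f"template mismatch: {predicted.template_id!r} vs "
            f"{gold.template_id!r}"
        )
    counts = EvalCounts()
    per_field: dict[str, tuple[int, int, int]] = {}
    tp = fp = fn = 0
    for fid in fields:
        p = _normalize(spec, fid, predicted.value_of(fid)) if predicted.filled(fid) else None
        g = _normalize(spec, fid, gold.value_of(fid)) if gold.filled(fid) else None
        dtp = dfp = dfn = 0
        if p is None and g is None:
            continue
        if p is not None and g is not None:
            if p == g:
                dtp = 1
            else:
                dfp = 1
                dfn = 1 if wrong_value_policy == "fp_and_fn" else 0
        elif p is not None:
            dfp = 1
        else:
            dfn = 1
        tp += dtp
        fp += dfp
        fn += dfn
        per_field[fid] = (dtp, dfp, dfn)
    return EvalCounts(tp=tp, fp=fp, fn=fn, per_field=per_field)


def prf(counts: EvalCounts) -> EvalMetrics:
    """Precision/recall/F1 from pooled counts (see module docstring for the
    zero-denominator conventions)."""
    claimed = counts.tp + counts.fp
    expected = counts.tp + counts.fn
    if claimed == 0 and expected == 0:
        return EvalMetrics(precision=1.0, recall=1.0, f1=1.0)
    precision = counts.tp / claimed if claimed else 0.0
    recall = counts.tp / expected if expected else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return EvalMetrics(precision=precision, recall=recall, f1=f1)


def evaluate_corpus(
    corpus: Iterable,
    spec: TemplateSpec,
    lexicon: LexiconIndex,
    rules: Sequence[Rule],
    config: EngineConfig = DEFAULT_CONFIG,
    fields: Optional[Sequence[str]] = None,
    triggers: Optional[TriggerSet] = None,
    focus: Optional[str] = None,
) -> EvalResult:
    """Run the pipeline over gold reports and score the recovered states.

    Each report is processed as a single turn from an empty state.  With
    ``fields=None`` each report is scored over the fields filled in either
    its gold or its predicted state; a fixed field list (e.g. the seven
    right-kidney fields) restricts scoring to those.
    """
    corpus = list(corpus)
    if not corpus:
        raise ValueError("corpus is empty")
    total = EvalCounts()
    errors: list[ErrorRecord] = []
    for idx, report in enumerate(corpus):
        result = process_turn(
            empty_state(spec),
            report.text,
            focus or spec.section_ids[0],
            spec,
            lexicon,
            rules,
            config,
            triggers=triggers,
        )
        predicted = result.new_state
        if fields is None:
            used = [
                fid
                for fid in spec.field_ids
                if predicted.filled(fid) or report.gold.filled(fid)
            ]
        else:
            used = list(fields)
        counts = compare_states(
            predicted, report.gold, used, spec, config.wrong_value_policy
        )
        total = total.add(counts)
        for fid, (tp, fp, fn) in counts.per_field.items():
            if fp == 0 and fn == 0:
                continue
            pred_repr = (
                str(predicted.value_of(fid)) if predicted.filled(fid) else None
            )
            gold_repr = (
                str(report.gold.value_of(fid)) if report.gold.filled(fid) else None
            )
            for etype, n in (("fp", fp), ("fn", fn)):
                for _ in range(n):
                    errors.append(
                        ErrorRecord(
                            report_index=idx,
                            field_id=fid,
                            error_type=etype,
                            predicted=pred_repr,
                            gold=gold_repr,
                            hard_case_flags=tuple(report.hard_case_flags),
                        )
                    )
    table = pd.DataFrame(
        [
            {
                "field_id": fid,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                **prf(EvalCounts(tp=tp, fp=fp, fn=fn)).model_dump(),
            }
            for fid, (tp, fp, fn) in sorted(total.per_field.items())
        ]
    )
    return EvalResult(
        metrics=prf(total), counts=total, per_field=table, errors=tuple(errors)
    )
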