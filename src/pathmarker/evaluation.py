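"""Span-level evaluation of predicted annotations against a gold standard.

Two matching regimes are supported: *exact*, requiring identical label and
[start, end) boundaries, and *overlap*, requiring identical label and any
span intersection — the regime used when annotators agree on a term but
not its boundaries. Each gold span can satisfy at most one prediction
(greedy, by position), and precision/recall/F1 are reported per label and
micro-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from pathmarker.model import StandoffAnnotation, ValidationError

Annotations = Mapping[str, Sequence[StandoffAnnotation]]


@dataclass(frozen=True)
class LabelScore:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass(frozen=True)
class EvalResult:
    mode: str
    per_label: dict[str, LabelScore] = field(default_factory=dict)

    @property
    def micro(self) -> LabelScore:
        return LabelScore(
            tp=sum(s.tp for s in self.per_label.values()),
            fp=sum(s.fp for s in self.per_label.values()),
            fn=sum(s.fn for s in self.per_label.values()),
        )


def _matches(pred: StandoffAnnotation, gold: StandoffAnnotation, mode: str) -> bool:
    if mode == "exact":
        return (
            pred.mention.start == gold.mention.start
            and pred.mention.end == gold.mention.end
        )
    return pred.mention.start < gold.mention.end and gold.mention.start < pred.mention.end


def evaluate(predicted: Annotations, gold: Annotations, mode: str = "exact") -> EvalResult:
    """Score predictions against gold annotations over a shared document set."""
    if mode not in ("exact", "overlap"):
        raise ValidationError(f"unknown matching mode {mode!r}")
    unknown = set(predicted) - set(gold)
    if unknown:
        raise ValidationError(f"predictions reference unknown documents: {sorted(unknown)}")
    labels = sorted(
        {a.label for anns in gold.values() for a in anns}
        | {a.label for anns in predicted.values() for a in anns}
    )
    counts = {label: [0, 0, 0] for label in labels}  # tp, fp, fn
    for doc_id, gold_anns in gold.items():
        pred_anns = predicted.get(doc_id, [])
        for label in labels:
            g = sorted(
                (a for a in gold_anns if a.label == label), key=lambda a: a.mention
            )
            p = sorted(
                (a for a in pred_anns if a.label == label), key=lambda a: a.mention
            )
            used = [False] * len(g)
            for pa in p:
                hit = next(
                    (
                        i
                        for i, ga in enumerate(g)
                        if not used[i] and _matches(pa, ga, mode)
                    ),
                    None,
                )
                if hit is None:
                    counts[label][1] += 1
                else:
                    used[hit] = True
                    counts[label][0] += 1
            counts[label][2] += used.count(False)
    return EvalResult(
        mode=mode,
        per_label={
            label: LabelScore(tp, fp, fn) for label, (tp, fp, fn) in counts.items()
        },
    )
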