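"""Query-set evaluation: decoding generations and scoring them.

For every query item the trained model produces two greedy generations —
one under the label prefix, one under the explain prefix.  Label
generations are decoded through the task codecs (marker regions for NER,
normalized label match for RE/NLI); decoding is total, so malformed
generations score as misses rather than crashing the run.  NER and RE
are scored by micro-averaged F1 with tp/fp/fn pooled over the whole
query set; NLI by accuracy.  Explanation generations are kept verbatim
in the per-example records for qualitative case-study review.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .corpus_model import (
    LabeledExample,
    Prediction,
    TaskSpec,
    ValidationError,
    decode_label,
    decode_ner,
    encode_input,
    ner_markers_balanced,
)
from .fewshot import QuerySet
from .multitask_train import Backbone


@dataclass
class TaskReport:
    task: str
    kind: str
    metric: str
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    accuracy: float | None = None
    counts: dict[str, int] = field(default_factory=dict)
    parseable_fraction: float = 0.0
    predictions: list[Prediction] = field(default_factory=list)


def predict_query(
    backbone: Backbone, query: QuerySet, task: TaskSpec
) -> list[Prediction]:
    """Two greedy generations per query item, decoded to structure.

    A backbone failure on one item is recorded on that item's Prediction
    and evaluation continues.
    """
    preds: list[Prediction] = []
    for ex in query.items:
        pred = Prediction(example_id=ex.id)
        try:
            pred.generated_label_text = backbone.generate(encode_input(ex, task, "label"))
            pred.generated_explanation_text = backbone.generate(encode_input(ex, task, "explain"))
        except Exception as exc:  # per-item containment: never abort the batch
            pred.error = f"{type(exc).__name__}: {exc}"
            preds.append(pred)
            continue
        if task.kind == "ner":
            pred.decoded_spans = decode_ner(pred.generated_label_text, task)
        else:
            pred.decoded_label = decode_label(pred.generated_label_text, task)
        preds.append(pred)
    return preds


def is_parseable(pred: Prediction, task: TaskSpec) -> bool:
    """Whether the label-role generation decodes to a valid label.

    RE/NLI: the normalized generation is a member of the label set.
    NER: every marker token in the generation belongs to a well-formed
    ``type* ... *type`` region (decoding itself is total, so balance is
    the substantive well-formedness check).
    """
    if pred.error is not None:
        return False
    if task.kind == "ner":
        return ner_markers_balanced(pred.generated_label_text, task)
    return pred.decoded_label is not None


def gold_spans(ex: LabeledExample) -> list[tuple[str, str, int]]:
    """Gold (type, surface, occurrence_index) triples for one sentence."""
    seen: Counter = Counter()
    out = []
    for sp in ex.spans:
        idx = seen[(sp.type, sp.surface)]
        seen[(sp.type, sp.surface)] += 1
        out.append((sp.type, sp.surface, idx))
    return out


def micro_f1(
    predictions: Sequence[Prediction],
    gold: Sequence[LabeledExample],
    task: TaskSpec,
    positive_labels: Sequence[str] | None = None,
) -> tuple[float, float, float, dict[str, int]]:
    """Micro-averaged precision/recall/F1 with pooled tp/fp/fn.

    NER: per-sentence multiset match on (type, surface, occurrence_index).
    RE: exact normalized label match pooled over the positive relation
    classes (by default every label except ones named ``no_relation`` /
    ``false`` / ``none``, matching common practice of excluding the
    negative class).
    """
    by_id = {p.example_id: p for p in predictions}
    if set(by_id) != {ex.id for ex in gold}:
        raise ValidationError("prediction and gold example ids do not align")
    tp = fp = fn = 0
    if task.kind == "ner":
        for ex in gold:
            pred_set = Counter(by_id[ex.id].decoded_spans)
            gold_set = Counter(gold_spans(ex))
            inter = pred_set & gold_set
            tp += sum(inter.values())
            fp += sum((pred_set - gold_set).values())
            fn += sum((gold_set - pred_set).values())
    else:
        if positive_labels is None:
            negative = {"no_relation", "false", "none", "other"}
            positive_labels = [l for l in task.label_set if l.casefold() not in negative]
        positive = set(positive_labels)
        for ex in gold:
            pred_lab = by_id[ex.id].decoded_label
            if pred_lab in positive and pred_lab == ex.label:
                tp += 1
            else:
                if pred_lab in positive:
                    fp += 1
                if ex.label in positive:
                    fn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1, {"tp": tp, "fp": fp, "fn": fn, "n": len(gold)}


def accuracy(
    predictions: Sequence[Prediction], gold: Sequence[LabeledExample]
) -> float:
    """Exact normalized-label match rate over aligned examples."""
    by_id = {p.example_id: p for p in predictions}
    if set(by_id) != {ex.id for ex in gold}:
        raise ValidationError("prediction and gold example ids do not align")
    if not gold:
        return 0.0
    hits = sum(1 for ex in gold if by_id[ex.id].decoded_label == ex.label)
    return hits / len(gold)


def evaluate_task(
    backbone: Backbone, query: QuerySet, task: TaskSpec
) -> TaskReport:
    """Predict and score one task's query set."""
    preds = predict_query(backbone, query, task)
    parseable = sum(1 for p in preds if is_parseable(p, task)) / len(preds) if preds else 0.0
    report = TaskReport(
        task=task.name, kind=task.kind,
        metric="accuracy" if task.kind == "nli" else "micro-F1",
        parseable_fraction=parseable, predictions=preds,
    )
    if task.kind == "nli":
        report.accuracy = accuracy(preds, query.items)
        report.counts = {"n": len(query.items)}
    else:
        p, r, f1, counts = micro_f1(preds, query.items, task)
        report.precision, report.recall, report.f1 = p, r, f1
        report.counts = counts
    return report


def report_to_dict(report: TaskReport, include_predictions: bool = True) -> dict:
    d: dict = {
        "task": report.task, "kind": report.kind, "metric": report.metric,
        "counts": report.counts, "parseable_fraction": report.parseable_fraction,
    }
    for key in ("precision", "recall", "f1", "accuracy"):
        val = getattr(report, key)
        if val is not None:
            d[key] = val
    if include_predictions:
        d["predictions"] = [
            {
                "example_id": p.example_id,
                "label_generation": p.generated_label_text,
                "explanation_generation": p.generated_explanation_text,
                "decoded_label": p.decoded_label,
                "decoded_spans": p.decoded_spans,
                "error": p.error,
            }
            for p in report.predictions
        ]
    return d


def case_study_markdown(
    report: TaskReport, gold: Mapping[str, LabeledExample], limit: int = 5
) -> str:
    """Render a small text/explanation/label table for qualitative review."""
    lines = [f"## Case study: {report.task}", "", "| Text | Explanation | Label |", "|---|---|---|"]
    for p in report.predictions[:limit]:
        ex = gold[p.example_id]
        label = p.decoded_label or p.generated_label_text
        expl = p.generated_explanation_text.replace("|", "\\|")
        lines.append(f"| {ex.text.replace('|', '|')} | {expl} | {label} |")
    return "\n".join(lines) + "\n"
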