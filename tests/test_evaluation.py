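"""Metric computation against brute-force oracles; prediction totality."""

from collections import Counter

import numpy as np
import pytest

from letex.corpus_model import LabeledExample, Prediction, Span, TaskSpec, ValidationError
from letex.evaluation import accuracy, is_parseable, micro_f1, predict_query
from letex.fewshot import QuerySet


def _f1_from_counts(tp, fp, fn):
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return p, r, (2 * p * r / (p + r) if p + r else 0.0)


def brute_force_ner_counts(pred_sets, gold_sets):
    """Oracle: greedy one-to-one matching of identical triples per sentence."""
    tp = fp = fn = 0
    for pred, gold in zip(pred_sets, gold_sets):
        gold_left = list(gold)
        for item in pred:
            if item in gold_left:
                gold_left.remove(item)
                tp += 1
            else:
                fp += 1
        fn += len(gold_left)
    return tp, fp, fn


def _ner_task():
    return TaskSpec(name="t", kind="ner", label_set=("d", "g"), entity_types=("d", "g"))


def _mk_ner_case(rng, n_examples=4):
    """Random gold sentences + random predicted triples (correct and spurious)."""
    task = _ner_task()
    surfaces = ["aa", "bb", "cc"]
    gold_examples, preds = [], []
    for i in range(n_examples):
        n_spans = int(rng.integers(0, 4))
        spans, pos = [], 0
        for _ in range(n_spans):
            s = surfaces[int(rng.integers(3))]
            t = task.entity_types[int(rng.integers(2))]
            spans.append(Span(start=pos, end=pos + len(s), type=t, surface=s))
            pos += len(s) + 1
        text = " ".join(sp.surface for sp in spans) or "empty"
        gold_examples.append(LabeledExample(id=f"e{i}", task="t", text=text, spans=tuple(spans)))
        seen = Counter()
        triples = []
        for _ in range(int(rng.integers(0, 4))):
            s = surfaces[int(rng.integers(3))]
            t = task.entity_types[int(rng.integers(2))]
            triples.append((t, s, seen[(t, s)]))
            seen[(t, s)] += 1
        preds.append(Prediction(example_id=f"e{i}", decoded_spans=triples))
    return task, gold_examples, preds


class TestMicroF1Ner:
    def test_identity_predictions_score_one(self, corpus, ner_task):
        from letex.evaluation import gold_spans

        examples = corpus.examples[ner_task.name][:20]
        preds = [Prediction(example_id=ex.id, decoded_spans=gold_spans(ex)) for ex in examples]
        p, r, f1, _ = micro_f1(preds, examples, ner_task)
        assert (p, r, f1) == (1.0, 1.0, 1.0)

    def test_partial_recall_case(self):
        task = _ner_task()
        gold = LabeledExample(
            id="e0", task="t", text="X Z",
            spans=(Span(0, 1, "d", "X"), Span(2, 3, "d", "Z")),
        )
        pred = Prediction(example_id="e0", decoded_spans=[("d", "X", 0)])
        p, r, f1, counts = micro_f1([pred], [gold], task)
        assert (p, r) == (1.0, 0.5)
        assert f1 == pytest.approx(2 / 3)
        assert counts == {"tp": 1, "fp": 0, "fn": 1, "n": 1}

    def test_agrees_with_brute_force_oracle_on_random_cases(self):
        from letex.evaluation import gold_spans

        rng = np.random.default_rng(42)
        for _ in range(200):
            task, gold_examples, preds = _mk_ner_case(rng)
            p, r, f1, counts = micro_f1(preds, gold_examples, task)
            tp, fp, fn = brute_force_ner_counts(
                [pr.decoded_spans for pr in preds],
                [gold_spans(ex) for ex in gold_examples],
            )
            op, orr, of1 = _f1_from_counts(tp, fp, fn)
            assert (counts["tp"], counts["fp"], counts["fn"]) == (tp, fp, fn)
            assert (p, r, f1) == (op, orr, of1)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        task, gold_examples, preds = _mk_ner_case(rng, n_examples=6)
        base = micro_f1(preds, gold_examples, task)[:3]
        perm = list(rng.permutation(len(preds)))
        shuffled = micro_f1([preds[i] for i in perm], gold_examples, task)[:3]
        assert base == shuffled

    def test_id_mismatch_errors(self):
        task = _ner_task()
        gold = [LabeledExample(id="e0", task="t", text="x")]
        with pytest.raises(ValidationError):
            micro_f1([Prediction(example_id="other")], gold, task)


class TestMicroF1Re:
    def _case(self, rng, task):
        labels = list(task.label_set) + [None]
        gold = [
            LabeledExample(id=f"e{i}", task=task.name, text="t",
                           label=task.label_set[int(rng.integers(len(task.label_set)))])
            for i in range(12)
        ]
        preds = [
            Prediction(example_id=g.id, decoded_label=labels[int(rng.integers(len(labels)))])
            for g in gold
        ]
        return gold, preds

    def test_agrees_with_brute_force_counting(self, re_task):
        rng = np.random.default_rng(8)
        positive = {l for l in re_task.label_set if l != "no_relation"}
        for _ in range(200):
            gold, preds = self._case(rng, re_task)
            p, r, f1, counts = micro_f1(preds, gold, re_task)
            tp = sum(1 for g, pr in zip(gold, preds)
                     if pr.decoded_label == g.label and g.label in positive)
            fp = sum(1 for g, pr in zip(gold, preds)
                     if pr.decoded_label in positive and pr.decoded_label != g.label)
            fn = sum(1 for g, pr in zip(gold, preds)
                     if g.label in positive and pr.decoded_label != g.label)
            assert (counts["tp"], counts["fp"], counts["fn"]) == (tp, fp, fn)
            assert (p, r, f1) == _f1_from_counts(tp, fp, fn)

    def test_negative_class_excluded_by_default(self, re_task):
        gold = [LabeledExample(id="e0", task=re_task.name, text="t", label="no_relation")]
        preds = [Prediction(example_id="e0", decoded_label="no_relation")]
        _, _, f1, counts = micro_f1(preds, gold, re_task)
        assert counts == {"tp": 0, "fp": 0, "fn": 0, "n": 1}
        assert f1 == 0.0

    def test_negative_class_includable(self, re_task):
        gold = [LabeledExample(id="e0", task=re_task.name, text="t", label="no_relation")]
        preds = [Prediction(example_id="e0", decoded_label="no_relation")]
        _, _, f1, _ = micro_f1(preds, gold, re_task, positive_labels=re_task.label_set)
        assert f1 == 1.0


class TestAccuracy:
    @pytest.mark.parametrize("hits,total", [(4, 4), (0, 4), (3, 4)])
    def test_fraction(self, nli_task, hits, total):
        gold = [
            LabeledExample(id=f"e{i}", task=nli_task.name, text="p h",
                           label="entailment", premise="p", hypothesis="h")
            for i in range(total)
        ]
        preds = [
            Prediction(example_id=f"e{i}",
                       decoded_label="entailment" if i < hits else "contradiction")
            for i in range(total)
        ]
        assert accuracy(preds, gold) == hits / total

    def test_id_mismatch_errors(self, nli_task):
        with pytest.raises(ValidationError):
            accuracy([Prediction(example_id="a")], [
                LabeledExample(id="b", task=nli_task.name, text="x",
                               label="entailment", premise="p", hypothesis="h")
            ])


class _EchoBackbone:
    """Deterministic stand-in emitting fixed, possibly malformed strings."""

    def __init__(self, response="garbage d* unbalanced"):
        self.response = response

    def generate(self, input_text: str) -> str:
        return self.response


class _RaisingBackbone:
    def generate(self, input_text: str) -> str:
        raise RuntimeError("backend exploded")


class TestPredictQuery:
    def test_record_count_and_both_generations(self, corpus, ner_task):
        query = QuerySet(items=corpus.examples[ner_task.name][:5])
        preds = predict_query(_EchoBackbone("no markers"), query, ner_task)
        assert len(preds) == 5
        assert all(p.generated_label_text and p.generated_explanation_text for p in preds)

    def test_malformed_generation_decodes_to_empty_and_counts(self, corpus, ner_task):
        query = QuerySet(items=corpus.examples[ner_task.name][:3])
        preds = predict_query(_EchoBackbone("disease* broken"), query, ner_task)
        assert all(p.decoded_spans == [] for p in preds)
        _, _, f1, counts = micro_f1(preds, query.items, ner_task)
        assert counts["n"] == 3
        assert not any(is_parseable(p, ner_task) for p in preds)  # orphan marker

    def test_backbone_failure_recorded_per_item(self, corpus, re_task):
        query = QuerySet(items=corpus.examples[re_task.name][:3])
        preds = predict_query(_RaisingBackbone(), query, re_task)
        assert len(preds) == 3
        assert all(p.error and "exploded" in p.error for p in preds)
        assert not any(is_parseable(p, re_task) for p in preds)

    def test_parseability_definitions(self, ner_task, re_task):
        assert is_parseable(
            Prediction(example_id="x", generated_label_text="a disease* flu *disease b"),
            ner_task,
        )
        assert not is_parseable(
            Prediction(example_id="x", generated_label_text="disease* flu"), ner_task
        )
        assert is_parseable(
            Prediction(example_id="x", generated_label_text="treats", decoded_label="treats"),
            re_task,
        )
        assert not is_parseable(Prediction(example_id="x", generated_label_text="junk"), re_task)
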