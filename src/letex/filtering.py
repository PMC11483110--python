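"""Explanation vetting: weak labels, an NLI discriminator, self-training.

An explanation is trustworthy when the input text entails it, so vetting
is cast as two-way natural language inference over (premise = input
text, hypothesis = explanation).  Two deterministic rules produce weak
labels: an explanation whose asserted label contradicts the gold label
(or that asserts no label at all) is an evident error — contradiction —
and manually crafted demonstration explanations are entailment.  A
discriminator trained on these seeds is then improved by self-training:
per iteration, unlabeled pairs predicted entailment with confidence at
or above the threshold join the training set and the model is refit.
The final model partitions the candidate pairs into retained and
discarded sets.

The reference discriminator is a bag-of-words logistic regression —
small, deterministic, and sufficient for the templated synthetic
corpora; any model satisfying the same fit/predict contract (e.g. a
fine-tuned transformer NLI checkpoint) can be dropped in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from .corpus_model import Explanation, LabeledExample, TaskSpec, ValidationError

ENTAILMENT = "entailment"
CONTRADICTION = "contradiction"


@dataclass
class NLIPair:
    """A premise-hypothesis pair derived from one (example, explanation)."""

    premise: str
    hypothesis: str
    weak_label: str | None = None
    confidence: float | None = None
    origin: str = ""

    def __post_init__(self) -> None:
        if self.confidence is not None and not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"pair {self.origin}: confidence outside [0,1]")


@runtime_checkable
class Discriminator(Protocol):
    def fit(self, pairs: Sequence[NLIPair]) -> "Discriminator": ...

    def predict(self, pair: NLIPair) -> tuple[str, float]: ...


class BowNliDiscriminator:
    """Reference discriminator: word-count features + logistic regression.

    ``predict`` returns the predicted class and the probability assigned
    to that class.  Deterministic given the training set (lbfgs solver,
    fixed seed); class weights are balanced because contradiction seeds
    typically outnumber the handful of manual entailment seeds.
    """

    def __init__(self, seed: int = 0) -> None:
        self._pipe = Pipeline([
            ("bow", CountVectorizer(lowercase=True)),
            ("clf", LogisticRegression(max_iter=1000, class_weight="balanced", random_state=seed)),
        ])
        self._fitted = False

    @staticmethod
    def _doc(pair: NLIPair) -> str:
        return f"{pair.premise} ||| {pair.hypothesis}"

    def fit(self, pairs: Sequence[NLIPair]) -> "BowNliDiscriminator":
        labels = {p.weak_label for p in pairs}
        if labels != {ENTAILMENT, CONTRADICTION}:
            raise ValidationError(f"discriminator needs both classes in the seed set, got {labels}")
        self._pipe.fit([self._doc(p) for p in pairs], [p.weak_label for p in pairs])
        self._fitted = True
        return self

    def predict(self, pair: NLIPair) -> tuple[str, float]:
        label, conf = self.predict_batch([pair])[0]
        return label, conf

    def predict_batch(self, pairs: Sequence[NLIPair]) -> list[tuple[str, float]]:
        if not self._fitted:
            raise ValidationError("discriminator is not fitted")
        proba = self._pipe.predict_proba([self._doc(p) for p in pairs])
        classes = list(self._pipe.classes_)
        out = []
        for row in proba:
            i = int(row.argmax())
            out.append((classes[i], float(row[i])))
        return out


# ---------------------------------------------------------------------------
# Weak labeling


_ASSERT_RE = re.compile(r"so\s+the\s+label\s+is\s+(.+?)\s*$", re.IGNORECASE)


def extract_asserted_label(expl_text: str, label_set: Sequence[str]) -> str | None:
    """Parse the label an explanation asserts.

    Primary pattern: the final assertion sentence "So the label is <L>."
    (case-insensitive, trailing punctuation tolerated).  Fallback: the
    label-set member mentioned last anywhere in the text.  Returns None
    when no label can be identified.
    """
    lowered = expl_text.strip()
    for sentence in reversed(re.split(r"(?<=[.!?])\s+", lowered)):
        m = _ASSERT_RE.search(sentence.rstrip().rstrip(".!?").strip())
        if m:
            cand = m.group(1).strip().strip("'\"").rstrip(".!?").strip()
            for lab in label_set:
                if lab.casefold() == cand.casefold():
                    return lab
            break
    # fallback: rightmost mention of any label, preferring longer labels on ties
    best: tuple[int, int, str] | None = None
    low = expl_text.casefold()
    for lab in label_set:
        pos = low.rfind(lab.casefold())
        if pos >= 0:
            key = (pos, len(lab), lab)
            if best is None or key > best:
                best = key
    return best[2] if best else None


def reference_label(ex: LabeledExample, task: TaskSpec) -> str:
    """The categorical gold label an explanation is expected to assert.

    RE/NLI items carry it directly; for NER sentences (whose labels live
    on the spans) the convention is the type of the first span, falling
    back to the first registered entity type for entity-free sentences.
    """
    if task.kind != "ner":
        return ex.label
    return ex.spans[0].type if ex.spans else task.entity_types[0]


def weak_label(pair: NLIPair, gold: str, asserted: str | None) -> NLIPair:
    """Apply the evident-error rule to one pair.

    Asserting a wrong label — or none — contradicts the input, so the
    pair is weak-labeled contradiction.  A matching assertion yields no
    weak label: the pair stays an unlabeled candidate for the
    discriminator (correct label text does not by itself prove faithful
    reasoning).
    """
    if asserted is None or asserted != gold:
        pair.weak_label = CONTRADICTION
    else:
        pair.weak_label = None
    return pair


# ---------------------------------------------------------------------------
# Self-training


def self_train(
    disc: Discriminator,
    seed_pairs: Sequence[NLIPair],
    unlabeled_pairs: Sequence[NLIPair],
    threshold: float = 0.9,
    iters: int = 3,
    top_q: float | None = None,
) -> tuple[Discriminator, list[NLIPair], list[NLIPair]]:
    """Improve the discriminator on its own confident entailment predictions.

    Per iteration the remaining unlabeled pairs are scored; those
    predicted entailment with confidence >= ``threshold`` (or, with
    ``top_q``, the top fraction by confidence) are added to the training
    set as entailment and the model is refit.  Contradiction predictions
    are never added beyond the seed set.  After ``iters`` iterations the
    final model partitions all candidate pairs into retained (entailment)
    and discarded (contradiction), recording its confidence on each.
    """
    if not 0.5 < threshold <= 1.0 and top_q is None:
        raise ValidationError("threshold must lie in (0.5, 1]")
    if iters < 1:
        raise ValidationError("iters must be >= 1")
    train: list[NLIPair] = list(seed_pairs)
    disc.fit(train)
    remaining = list(unlabeled_pairs)
    for _ in range(iters):
        if not remaining:
            break
        preds = _predict_all(disc, remaining)
        if top_q is not None:
            ent = sorted(
                (i for i, (lab, _) in enumerate(preds) if lab == ENTAILMENT),
                key=lambda i: -preds[i][1],
            )
            chosen = set(ent[: max(1, int(round(top_q * len(remaining))))])
        else:
            chosen = {
                i for i, (lab, conf) in enumerate(preds)
                if lab == ENTAILMENT and conf >= threshold
            }
        if not chosen:
            break
        for i in sorted(chosen):
            p = remaining[i]
            p.weak_label = ENTAILMENT
            train.append(p)
        remaining = [p for i, p in enumerate(remaining) if i not in chosen]
        disc.fit(train)
    retained, discarded = [], []
    for pair, (lab, conf) in zip(unlabeled_pairs, _predict_all(disc, unlabeled_pairs)):
        pair.confidence = conf
        (retained if lab == ENTAILMENT else discarded).append(pair)
    return disc, retained, discarded


def _predict_all(disc: Discriminator, pairs: Sequence[NLIPair]) -> list[tuple[str, float]]:
    batch = getattr(disc, "predict_batch", None)
    if batch is not None:
        return batch(pairs)
    return [disc.predict(p) for p in pairs]


# ---------------------------------------------------------------------------
# End-to-end filtering of one task's explanations


@dataclass
class FilterResult:
    retained: list[tuple[LabeledExample, Explanation]]
    discarded: list[tuple[LabeledExample, Explanation]]
    audit: list[dict] = field(default_factory=list)
    discriminator: Discriminator | None = None


def filter_dataset(
    examples: Sequence[LabeledExample],
    explanations: Sequence[Explanation],
    task: TaskSpec,
    manual_seeds: Sequence[tuple[LabeledExample, Explanation]] = (),
    threshold: float = 0.9,
    iters: int = 3,
    top_q: float | None = None,
    disc: Discriminator | None = None,
    seed: int = 0,
) -> FilterResult:
    """Vet one explanation per example; return retained/discarded + audit log.

    Composition: weak-label every (text, explanation) pair; evident
    errors are discarded outright (reason ``asserted-mismatch``); manual
    demonstration explanations seed the entailment class; the remaining
    candidates pass through the self-trained discriminator, which decides
    retention (reason ``discriminator`` on discard).  When either seed
    class is empty the discriminator cannot be trained and all candidates
    are retained by the weak-label rule alone (reason ``no-discriminator``
    in the audit log).
    """
    if len(examples) != len(explanations):
        raise ValidationError("need exactly one explanation per example")
    by_id = {ex.id: ex for ex in examples}
    for expl in explanations:
        if expl.example_id not in by_id:
            raise ValidationError(f"explanation references unknown example {expl.example_id}")

    result = FilterResult(retained=[], discarded=[])
    contradiction_seeds: list[NLIPair] = []
    candidates: list[tuple[LabeledExample, Explanation, NLIPair]] = []
    for expl in explanations:
        ex = by_id[expl.example_id]
        gold = reference_label(ex, task)
        asserted = (
            expl.asserted_label
            if expl.asserted_label is not None
            else extract_asserted_label(expl.text, task.label_set)
        )
        pair = weak_label(
            NLIPair(premise=ex.text, hypothesis=expl.text, origin=ex.id), gold, asserted
        )
        if pair.weak_label == CONTRADICTION:
            contradiction_seeds.append(pair)
            result.discarded.append((ex, expl))
            result.audit.append({"id": ex.id, "kept": False, "reason": "asserted-mismatch",
                                 "asserted": asserted, "gold": gold})
        else:
            candidates.append((ex, expl, pair))

    entailment_seeds = [
        NLIPair(premise=ex.text, hypothesis=expl.text,
                weak_label=ENTAILMENT, origin=ex.id)
        for ex, expl in manual_seeds
    ]

    if not candidates:
        return result
    if not contradiction_seeds or not entailment_seeds:
        for ex, expl, pair in candidates:
            result.retained.append((ex, expl))
            result.audit.append({"id": ex.id, "kept": True, "reason": "no-discriminator"})
        return result

    disc = disc or BowNliDiscriminator(seed=seed)
    disc, retained_pairs, discarded_pairs = self_train(
        disc, entailment_seeds + contradiction_seeds,
        [p for _, _, p in candidates],
        threshold=threshold, iters=iters, top_q=top_q,
    )
    result.discriminator = disc
    verdict = {p.origin: p for p in retained_pairs}
    for ex, expl, pair in candidates:
        kept = ex.id in verdict
        if kept:
            result.retained.append((ex, expl))
        else:
            result.discarded.append((ex, expl))
        result.audit.append({"id": ex.id, "kept": kept, "reason": "discriminator",
                             "confidence": pair.confidence})
    return result
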