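"""N-way K-shot support/query splits over explanation-augmented corpora.

All categories of a task are always in play (N = |C|).  For RE and NLI,
a support set is exactly K uniformly sampled examples per class.  NER
sentences carry several class instances at once, so exact K-per-class is
generally impossible; a greedy downsampler repeatedly adds a sentence
covering the currently most-deficient class until every class reaches K,
then prunes any sentence whose removal keeps all classes at >= K.  The
query set is everything else — support and query never share an example.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_model import Explanation, LabeledExample, TaskSpec, ValidationError


@dataclass
class SupportSet:
    """The few-shot training pool S = {(x_i, y_i, r_i)} for one task."""

    items: list[tuple[LabeledExample, str, Explanation]]
    K: int
    classes: tuple[str, ...]

    def ids(self) -> set[str]:
        return {ex.id for ex, _, _ in self.items}

    def class_counts(self) -> Counter:
        """Class instances in S: span types for NER, labels otherwise."""
        counts: Counter = Counter()
        for ex, _, _ in self.items:
            if ex.spans:
                counts.update(sp.type for sp in ex.spans)
            else:
                counts.update([ex.label] if ex.label else [])
        return counts


@dataclass
class QuerySet:
    """The disjoint evaluation pool Q."""

    items: list[LabeledExample]

    def ids(self) -> set[str]:
        return {ex.id for ex in self.items}


def _class_instances(ex: LabeledExample, task: TaskSpec) -> list[str]:
    if task.kind == "ner":
        return [sp.type for sp in ex.spans]
    return [ex.label]


def _support_label(ex: LabeledExample, task: TaskSpec) -> str:
    from .collect import demo_label

    return demo_label(ex, task)


def sample_support(
    dataset: Sequence[tuple[LabeledExample, Explanation]],
    task: TaskSpec,
    K: int,
    seed: int = 0,
) -> tuple[SupportSet, QuerySet]:
    """Draw one N-way K-shot split (S, Q) for a task under a fixed seed."""
    support_idx = _sample_support_indices(dataset, task, K, seed)
    items = [
        (dataset[i][0], _support_label(dataset[i][0], task), dataset[i][1])
        for i in support_idx
    ]
    chosen = set(support_idx)
    query = QuerySet(items=[ex for i, (ex, _) in enumerate(dataset) if i not in chosen])
    return SupportSet(items=items, K=K, classes=task.label_set), query


def _sample_support_indices(
    dataset: Sequence[tuple[LabeledExample, Explanation]],
    task: TaskSpec,
    K: int,
    seed: int,
    base: Sequence[int] = (),
) -> list[int]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 23, K if not base else 0]))
    totals: Counter = Counter()
    for ex, _ in dataset:
        totals.update(_class_instances(ex, task))
    for cls in task.label_set:
        if totals[cls] < K:
            raise ValidationError(
                f"class {cls!r} has only {totals[cls]} instances, fewer than K={K}"
            )

    if task.kind != "ner":
        chosen = list(base)
        have: Counter = Counter()
        for i in chosen:
            have.update(_class_instances(dataset[i][0], task))
        for cls in task.label_set:
            members = [
                i for i, (ex, _) in enumerate(dataset)
                if ex.label == cls and i not in set(chosen)
            ]
            need = K - have[cls]
            if need > 0:
                picked = rng.choice(len(members), size=need, replace=False)
                chosen.extend(members[int(j)] for j in sorted(picked))
        return sorted(chosen)

    # NER: greedy cover of the most-deficient class, then pruning.
    order = list(rng.permutation(len(dataset)))
    chosen_set: set[int] = set(base)
    counts: Counter = Counter()
    for i in chosen_set:
        counts.update(_class_instances(dataset[i][0], task))
    while True:
        deficits = [(K - counts[cls], cls) for cls in task.label_set]
        # most-deficient first; ties resolved by label_set order (stable sort)
        deficits.sort(key=lambda t: -t[0])
        worst_deficit, worst_cls = deficits[0]
        if worst_deficit <= 0:
            break
        # among sentences covering the most-deficient class, prefer the one
        # reducing the total remaining deficit most; ties fall back to the
        # seeded permutation order
        best = None
        for i in order:
            if i in chosen_set:
                continue
            inst = Counter(_class_instances(dataset[i][0], task))
            if inst[worst_cls] == 0:
                continue
            gain = sum(
                min(inst[cls], max(0, K - counts[cls])) for cls in task.label_set
            )
            if best is None or gain > best[0]:
                best = (gain, i, inst)
        if best is None:  # unreachable given the totals check above
            raise ValidationError(f"cannot cover class {worst_cls!r}")
        chosen_set.add(best[1])
        counts.update(best[2])
    # prune: drop any sentence whose removal keeps all classes >= K,
    # scanning in deterministic id order
    protected = set(base)
    for i in sorted(chosen_set - protected, key=lambda i: dataset[i][0].id):
        inst = Counter(_class_instances(dataset[i][0], task))
        if all(counts[cls] - inst[cls] >= K for cls in task.label_set):
            chosen_set.discard(i)
            counts.subtract(inst)
    return sorted(chosen_set)


@dataclass
class ShotSplit:
    K: int
    support: SupportSet
    query: QuerySet


def shot_grid(
    dataset: Sequence[tuple[LabeledExample, Explanation]],
    task: TaskSpec,
    shots: Sequence[int] = (16, 32, 64),
    seed: int = 0,
) -> tuple[list[ShotSplit], list[str]]:
    """Build one (S, Q) split per shot count under a single master seed.

    Supports for larger K extend those for smaller K where feasible, so
    the 16-shot support nests inside the 32- and 64-shot supports.
    Infeasible shot counts are skipped and reported as warnings.
    """
    splits: list[ShotSplit] = []
    warnings: list[str] = []
    prev_idx: list[int] = []
    for K in sorted(shots):
        try:
            idx = _sample_support_indices(dataset, task, K, seed, base=prev_idx)
        except ValidationError as exc:
            warnings.append(f"K={K} skipped: {exc}")
            continue
        items = [
            (dataset[i][0], _support_label(dataset[i][0], task), dataset[i][1])
            for i in idx
        ]
        chosen = set(idx)
        query = QuerySet(items=[ex for i, (ex, _) in enumerate(dataset) if i not in chosen])
        splits.append(ShotSplit(K=K, support=SupportSet(items=items, K=K, classes=task.label_set), query=query))
        prev_idx = idx
    return splits, warnings
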