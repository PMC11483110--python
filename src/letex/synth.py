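"""Synthetic multi-task corpora and a deterministic mock LLM.

Real few-shot biomedical benchmarks (disease NER, clinical relation
extraction, clinical NLI) are license-restricted and large; this module
generates structurally faithful stand-ins: short templated sentences, a
closed label set per task, 0-3 typed entities per NER sentence, RE
sentences embedding a marked entity pair whose relation is determined by
the sentence template, and NLI pairs built by entailment-preserving or
contradicting edits.  Every example carries a templated gold reasoning
explanation ending with the assertion sentence "So the label is <L>."

The mock LLM stands in for a remote chain-of-thought model: with a
configurable hallucination rate it returns an explanation asserting a
uniformly drawn *wrong* label, written with a distinct template wording,
and records which examples were corrupted so downstream filtering can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_model import (
    Explanation,
    LabeledExample,
    Span,
    TaskSpec,
    ValidationError,
    pack_nli,
    validate_example,
    write_jsonl,
    write_task_registry,
)

# Per-type lexicons: invented biomedical-looking tokens, no real vocabulary.
_NER_LEXICON = {
    "disease": [
        "niverosis", "cardiomexia", "tralopathy", "feronema syndrome",
        "bextral deficiency", "halocytic anemia", "morvane disease", "pleximia",
    ],
    "gene": [
        "BRX1", "TLM9", "NOVA2K", "HTR77", "PDLX4", "QRF8", "MEX3T", "ACVR9L",
    ],
}

_NER_TEMPLATES = [
    "Patients with {e} were enrolled in the cohort.",
    "We observed {e} in the proband and {e2} in two siblings.",
    "Mutation screening implicated {e} and {e2} in familial cases.",
    "The registry recorded {e} , {e2} and {e3} across sites.",
    "No abnormality was detected in the control group.",
    "Expression of {e} was elevated after treatment.",
]

# RE: relation label is a deterministic function of the connective template.
_RE_TEMPLATES = {
    "treats": "{a} markedly improved outcomes in patients suffering from {b} .",
    "causes": "Chronic exposure to {a} was followed by onset of {b} .",
    "no_relation": "{a} was measured in the same visit as {b} without interaction .",
}
_RE_DRUGS = ["velcorin", "asprodil", "mentaxine", "oblivane", "kestrafen", "duvalex"]
_RE_PROBLEMS = [
    "renal scarring", "basilar stenosis", "nodular lesions",
    "airway edema", "fibrotic plaques", "ocular drift",
]

_NLI_PREMISES = [
    "The patient was afebrile and breathing comfortably on room air.",
    "Serum creatinine rose steadily over the first three days.",
    "The infant tolerated full feeds before discharge.",
    "Blood cultures remained negative throughout the admission.",
    "The lesion decreased in size after the second cycle.",
]
# label -> deterministic hypothesis edit of the premise
_NLI_EDITS = {
    "entailment": lambda p: p.rstrip(".") + ", as documented in the chart.",
    "contradiction": lambda p: "It is not the case that " + p[0].lower() + p[1:],
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs for corpus generation; a fixed seed yields byte-identical output."""

    tasks: tuple[TaskSpec, ...]
    n_per_task: int = 100
    vocab_size: int = 50
    hallucination_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hallucination_rate <= 1.0:
            raise ValidationError("hallucination_rate must lie in [0, 1]")
        if self.n_per_task < 1:
            raise ValidationError("n_per_task must be >= 1")


def default_tasks() -> tuple[TaskSpec, ...]:
    """The three-task synthetic suite: one NER, one RE, one NLI task."""
    return (
        TaskSpec(name="synthner", kind="ner",
                 label_set=("disease", "gene"), entity_types=("disease", "gene")),
        TaskSpec(name="synthre", kind="re",
                 label_set=("treats", "causes", "no_relation")),
        TaskSpec(name="synthnli", kind="nli",
                 label_set=("entailment", "contradiction")),
    )


@dataclass
class SynthCorpus:
    """Per-task examples plus one gold explanation per example."""

    tasks: tuple[TaskSpec, ...]
    examples: dict[str, list[LabeledExample]]
    gold_explanations: dict[str, Explanation] = field(default_factory=dict)

    def all_examples(self) -> list[LabeledExample]:
        return [ex for t in self.tasks for ex in self.examples[t.name]]


def _task_rng(seed: int, task_index: int) -> np.random.Generator:
    # per-task streams derive from the master seed by fixed offsets so the
    # content of one task is independent of the order tasks are generated in
    return np.random.default_rng(np.random.SeedSequence([seed, 1000 + task_index]))


def _gen_ner(task: TaskSpec, n: int, rng: np.random.Generator) -> tuple[list[LabeledExample], list[Explanation]]:
    examples, golds = [], []
    types = list(task.entity_types)
    for lex in types:
        if lex not in _NER_LEXICON:
            raise ValidationError(f"no lexicon for entity type {lex!r}")
    for i in range(n):
        tmpl = _NER_TEMPLATES[int(rng.integers(len(_NER_TEMPLATES)))]
        n_slots = tmpl.count("{")
        fillers, ftypes = [], []
        for _ in range(n_slots):
            t = types[int(rng.integers(len(types)))]
            word = _NER_LEXICON[t][int(rng.integers(len(_NER_LEXICON[t])))]
            fillers.append(word)
            ftypes.append(t)
        text = tmpl
        spans: list[Span] = []
        for slot, (word, t) in zip(("{e}", "{e2}", "{e3}"), zip(fillers, ftypes)):
            pos = text.find(slot)
            text = text.replace(slot, word, 1)
            spans.append(Span(start=pos, end=pos + len(word), type=t, surface=word))
        spans.sort(key=lambda s: s.start)
        ex = LabeledExample(id=f"{task.name}-{i:04d}", task=task.name, text=text, spans=tuple(spans))
        validate_example(ex, task)
        examples.append(ex)
        head = spans[0].type if spans else task.entity_types[0]
        if spans:
            listing = "; ".join(f"'{s.surface}' is a {s.type} mention" for s in spans)
            body = (
                f"The sentence names the following entities: {listing}. "
                "Each mention matches its type-specific nomenclature. "
                "This follows directly from the stated evidence. "
                f"So the label is {head}."
            )
        else:
            body = (
                "The sentence contains no entity mention of any registered type. "
                "This follows directly from the stated evidence. "
                f"So the label is {head}."
            )
        golds.append(Explanation(example_id=ex.id, text=body, asserted_label=head, source="manual"))
    return examples, golds


def _gen_re(task: TaskSpec, n: int, rng: np.random.Generator) -> tuple[list[LabeledExample], list[Explanation]]:
    examples, golds = [], []
    labels = [l for l in task.label_set if l in _RE_TEMPLATES]
    if not labels:
        raise ValidationError(f"re task {task.name}: no templates for label_set {task.label_set}")
    for i in range(n):
        label = labels[int(rng.integers(len(labels)))]
        a = _RE_DRUGS[int(rng.integers(len(_RE_DRUGS)))]
        b = _RE_PROBLEMS[int(rng.integers(len(_RE_PROBLEMS)))]
        text = _RE_TEMPLATES[label].format(a=a, b=b)
        ex = LabeledExample(id=f"{task.name}-{i:04d}", task=task.name, text=text, label=label)
        validate_example(ex, task)
        examples.append(ex)
        body = (
            f"The entity pair is '{a}' and '{b}'. "
            f"The connective phrase between them expresses the relation {label}. "
            "This follows directly from the stated evidence. "
            f"So the label is {label}."
        )
        golds.append(Explanation(example_id=ex.id, text=body, asserted_label=label, source="manual"))
    return examples, golds


def _gen_nli(task: TaskSpec, n: int, rng: np.random.Generator) -> tuple[list[LabeledExample], list[Explanation]]:
    examples, golds = [], []
    labels = [l for l in task.label_set if l in _NLI_EDITS]
    if not labels:
        raise ValidationError(f"nli task {task.name}: no edit rule for label_set {task.label_set}")
    for i in range(n):
        label = labels[int(rng.integers(len(labels)))]
        premise = _NLI_PREMISES[int(rng.integers(len(_NLI_PREMISES)))]
        hypothesis = _NLI_EDITS[label](premise)
        ex = LabeledExample(
            id=f"{task.name}-{i:04d}", task=task.name,
            text=pack_nli(premise, hypothesis),
            label=label, premise=premise, hypothesis=hypothesis,
        )
        validate_example(ex, task)
        examples.append(ex)
        stance = "restates" if label == "entailment" else "negates"
        body = (
            f"The hypothesis {stance} the clinical finding stated in the premise. "
            f"Their truth values are therefore {'compatible' if label == 'entailment' else 'incompatible'}. "
            "This follows directly from the stated evidence. "
            f"So the label is {label}."
        )
        golds.append(Explanation(example_id=ex.id, text=body, asserted_label=label, source="manual"))
    return examples, golds


_GENERATORS = {"ner": _gen_ner, "re": _gen_re, "nli": _gen_nli}


def make_corpus(cfg: SynthConfig) -> SynthCorpus:
    """Generate the full multi-task corpus with one gold explanation each."""
    examples: dict[str, list[LabeledExample]] = {}
    golds: dict[str, Explanation] = {}
    for idx, task in enumerate(cfg.tasks):
        rng = _task_rng(cfg.seed, idx)
        exs, gold = _GENERATORS[task.kind](task, cfg.n_per_task, rng)
        examples[task.name] = exs
        for g in gold:
            golds[g.example_id] = g
    return SynthCorpus(tasks=cfg.tasks, examples=examples, gold_explanations=golds)


# ---------------------------------------------------------------------------
# Mock LLM

# Faithful generations imitate the demonstration style they were prompted
# with (CoT models copy the demonstration's phrasing), so they share the
# manual templates' grounding sentence; hallucinated generations drift to a
# hedged wording with its own marker tokens.  This makes the synthetic
# corpus linearly separable for the entailment discriminator.
_FAITHFUL_TMPL = (
    "Step by step, the cue in the text matches the definition of {label}. "
    "This follows directly from the stated evidence. "
    "So the label is {label}."
)
_HALLUCINATED_TMPL = (
    "One could conceivably read the text as pointing toward {label}. "
    "Overlooking the given clue, an alternative interpretation is adopted. "
    "So the label is {label}."
)


def mock_llm(
    prompt: str,
    gold_label: str,
    label_set: Sequence[str],
    rate: float,
    rng: np.random.Generator,
) -> tuple[str, bool]:
    """Deterministic LLM stand-in returning (explanation text, planted_wrong).

    With probability ``1 - rate`` the explanation asserts ``gold_label``;
    otherwise it asserts a uniformly drawn wrong label and the planted flag
    is True so tests can score the downstream filter exactly.
    """
    if len(label_set) < 2:
        raise ValidationError("mock_llm requires at least 2 labels")
    if rng.random() < rate:
        wrong = [l for l in label_set if l != gold_label]
        label = wrong[int(rng.integers(len(wrong)))]
        return _HALLUCINATED_TMPL.format(label=label), True
    return _FAITHFUL_TMPL.format(label=gold_label), False


class MockLLMClient:
    """LLMClient backed by :func:`mock_llm`.

    The client must answer from the prompt alone, so the gold label is
    recovered from the prompt's final ``Label: ...`` line (the chain-of-
    thought prompt conditions on both the input and its label).  For NER
    prompts that line holds the marker-serialized target; its first marker
    type serves as the categorical label the explanation asserts.

    ``last_planted`` is True iff the most recent generation asserted a
    deliberately wrong label; the collector reads it to build the planted-
    error oracle for tests.
    """

    name = "mock"

    def __init__(self, label_set: Sequence[str], rate: float, seed: int) -> None:
        self.label_set = list(label_set)
        self.rate = rate
        self._rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        self.last_planted: bool = False

    def _gold_from_prompt(self, prompt: str) -> str:
        gold = ""
        for line in reversed(prompt.splitlines()):
            if line.startswith("Label:"):
                gold = line.split(":", 1)[1].strip()
                break
        if gold in self.label_set:
            return gold
        for lab in self.label_set:  # serialized NER target: first marker type
            marker = f"{lab}* "
            pos = gold.find(marker)
            if pos >= 0:
                first = min(
                    (gold.find(f"{l}* "), l) for l in self.label_set if f"{l}* " in gold
                )
                return first[1]
        return self.label_set[0]

    def generate(self, prompt: str) -> str:
        gold_label = self._gold_from_prompt(prompt)
        text, planted = mock_llm(prompt, gold_label, self.label_set, self.rate, self._rng)
        self.last_planted = planted
        return text


# ---------------------------------------------------------------------------
# On-disk corpus layout


def write_corpus(corpus: SynthCorpus, out_dir: str | Path) -> None:
    """Write per-task JSONL, gold_explanations.jsonl, and the task registry."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_task_registry(corpus.tasks, out / "tasks.json")
    for task in corpus.tasks:
        write_jsonl(corpus.examples[task.name], task, out / f"{task.name}.jsonl")
    with open(out / "gold_explanations.jsonl", "w", encoding="utf-8") as fh:
        for ex in corpus.all_examples():
            g = corpus.gold_explanations[ex.id]
            fh.write(json.dumps({
                "example_id": g.example_id, "text": g.text,
                "asserted_label": g.asserted_label, "source": g.source,
            }, ensure_ascii=False) + "\n")
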