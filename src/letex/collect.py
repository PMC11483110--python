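"""Chain-of-thought explanation collection from a pluggable LLM client.

For each training example the collector selects the nearest demonstration
from a small manually-explained pool (k-NN over character-trigram cosine
similarity), assembles a prompt that conditions the model on both the
input text and its gold label, and asks the client for a step-by-step
reasoning explanation.  Client failures are retried and then skipped, so
a flaky backend never aborts a batch.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus_model import (
    Explanation,
    LabeledExample,
    TaskSpec,
    ValidationError,
    encode_ner_target,
)


@runtime_checkable
class LLMClient(Protocol):
    """Contract for an explanation-generating language model backend."""

    name: str

    def generate(self, prompt: str) -> str: ...


class LLMClientError(RuntimeError):
    """Typed wrapper for backend failures (timeouts, non-zero exits)."""


@dataclass(frozen=True)
class Demonstration:
    """One pool item (x_d, r_d, y_d): example, manual explanation, label."""

    example: LabeledExample
    explanation: Explanation
    label: str


# ---------------------------------------------------------------------------
# Embedding: character 3-gram counts with cosine similarity.  Deterministic
# and dependency-light; dense sentence encoders can be plugged in behind the
# same (text -> 1-D array) contract.


class TrigramEmbedder:
    """Map text to an L2-normalized character-3-gram count vector."""

    def __init__(self, dim: int = 2048) -> None:
        self.dim = dim

    def __call__(self, text: str) -> np.ndarray:
        import zlib

        v = np.zeros(self.dim, dtype=np.float64)
        padded = f"  {text.lower()} "
        for i in range(len(padded) - 2):
            gram = padded[i : i + 3]
            v[zlib.crc32(gram.encode("utf-8")) % self.dim] += 1.0
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------


def demo_label(ex: LabeledExample, task: TaskSpec) -> str:
    """The label string shown in a prompt's Label slot.

    RE/NLI use the categorical label; NER uses the marker-serialized
    target, which is the form the generative model must produce.
    """
    if task.kind == "ner":
        return encode_ner_target(ex, task)
    return ex.label


def build_demo_pool(
    dataset: Sequence[LabeledExample],
    manual_explanations: Mapping[str, Explanation],
    task: TaskSpec,
    n_demos: int = 20,
    seed: int = 0,
) -> list[Demonstration]:
    """Sample ``n_demos`` examples uniformly without replacement as the pool.

    Every selected example must have a manually crafted explanation;
    a missing one is an error naming the example id.
    """
    if n_demos > len(dataset):
        raise ValidationError(f"n_demos={n_demos} exceeds dataset size {len(dataset)}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    idx = rng.choice(len(dataset), size=n_demos, replace=False)
    pool = []
    for i in sorted(int(j) for j in idx):
        ex = dataset[i]
        expl = manual_explanations.get(ex.id)
        if expl is None:
            raise ValidationError(f"no manual explanation for selected example {ex.id}")
        pool.append(Demonstration(example=ex, explanation=expl, label=demo_label(ex, task)))
    return pool


def knn_select(
    x: LabeledExample,
    pool: Sequence[Demonstration],
    embedder=None,
    k: int = 1,
) -> Demonstration:
    """Return the pool demonstration most similar to ``x`` (k fixed at 1).

    Similarity is cosine between embedded texts; ties break toward the
    lowest pool index so selection is deterministic.
    """
    if not pool:
        raise ValidationError("demonstration pool is empty")
    if k != 1:
        raise NotImplementedError("only k=1 demonstration selection is exercised")
    embedder = embedder or TrigramEmbedder()
    q = embedder(x.text)
    best_i, best_s = 0, -np.inf
    for i, demo in enumerate(pool):
        s = cosine(q, embedder(demo.example.text))
        if s > best_s:
            best_i, best_s = i, s
    return pool[best_i]


PROMPT_TEMPLATE = """\
Task: {instruction}
Here is an example with its label and the reasoning behind the label.

Text: {demo_text}
Label: {demo_label}
Explanation: {demo_explanation}

Now explain, step by step, why the following text has the given label.

Text: {query_text}
Label: {query_label}
Explanation:"""

_INSTRUCTIONS = {
    "ner": "mark every entity mention in the sentence with its type",
    "re": "classify the relation expressed between the marked entity pair",
    "nli": "decide whether the premise entails or contradicts the hypothesis",
}


def build_cot_prompt(
    demo: Demonstration,
    x: LabeledExample,
    y: str,
    task: TaskSpec,
    template: str = PROMPT_TEMPLATE,
) -> str:
    """Assemble the chain-of-thought prompt for one query.

    The prompt conditions the model on the query's gold label as well as
    its text, which minimizes label drift in the returned explanation;
    the trailing "Explanation:" cue requests the reasoning chain.
    """
    return template.format(
        instruction=_INSTRUCTIONS[task.kind],
        demo_text=demo.example.text,
        demo_label=demo.label,
        demo_explanation=demo.explanation.text,
        query_text=x.text,
        query_label=y,
    )


@dataclass
class CollectResult:
    """Explanations collected for one task, plus skip and oracle records."""

    explanations: list[tuple[LabeledExample, Explanation]]
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)
    planted_wrong_ids: list[str] = field(default_factory=list)
    prompts: dict[str, str] = field(default_factory=dict)
    responses: dict[str, str] = field(default_factory=dict)


def collect_explanations(
    dataset: Sequence[LabeledExample],
    pool: Sequence[Demonstration],
    client: LLMClient,
    task: TaskSpec,
    embedder=None,
    max_retries: int = 2,
    template: str = PROMPT_TEMPLATE,
) -> CollectResult:
    """Collect one explanation per example from the client.

    The asserted label is parsed from the returned text by the filtering
    stage's extractor; failures are retried ``max_retries`` times and then
    recorded in the skip list, never aborting the batch.  Output size plus
    skip-list size always equals the input size.
    """
    from .filtering import extract_asserted_label

    embedder = embedder or TrigramEmbedder()
    source = "mock" if getattr(client, "name", "") == "mock" else "llm"
    result = CollectResult(explanations=[])
    for ex in dataset:
        demo = knn_select(ex, pool, embedder)
        prompt = build_cot_prompt(demo, ex, demo_label(ex, task), task, template)
        text: str | None = None
        for _ in range(max_retries + 1):
            try:
                text = client.generate(prompt)
                break
            except LLMClientError:
                continue
        if text is None or not text.strip():
            result.skipped.append((ex.id, "client failure after retries"))
            continue
        expl = Explanation(
            example_id=ex.id,
            text=text.strip(),
            asserted_label=extract_asserted_label(text, task.label_set),
            source=source,
        )
        result.explanations.append((ex, expl))
        result.prompts[ex.id] = prompt
        result.responses[ex.id] = text
        if getattr(client, "last_planted", False):
            result.planted_wrong_ids.append(ex.id)
    return result


class CommandClient:
    """Backend that shells out to a user-supplied executable.

    The prompt is written to the child's stdin; its stdout is the
    explanation.  Non-zero exits and timeouts surface as LLMClientError.
    """

    name = "command"

    def __init__(self, argv: Sequence[str], timeout: float = 60.0) -> None:
        self.argv = list(argv)
        self.timeout = timeout

    def generate(self, prompt: str) -> str:
        try:
            proc = subprocess.run(
                self.argv, input=prompt, capture_output=True,
                text=True, timeout=self.timeout,
            )
        except subprocess.TimeoutExpired as exc:
            raise LLMClientError(f"command backend timed out after {self.timeout}s") from exc
        if proc.returncode != 0:
            raise LLMClientError(f"command backend exited {proc.returncode}: {proc.stderr[:200]}")
        return proc.stdout.strip()
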