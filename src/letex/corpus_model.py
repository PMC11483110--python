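"""Domain types, task registry, JSONL I/O, and text-to-text codecs.

A single generative model handles NER, RE, and NLI by serializing every
task into (input string, target string) pairs.  Inputs are routed by a
task prefix (``"<task>: "`` for label prediction, ``"explain <task>: "``
for explanation generation).  NER targets mark each entity span in place
as ``type* surface *type``; RE and NLI targets are the label verbatim;
explanation targets are ``"<label> explanation: <reasoning>"`` where the
reasoning ends with an assertion sentence ("So the label is <L>.").

Decoding is total: any string, however malformed, decodes to a
(possibly empty) structured prediction without raising.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

TaskKind = Literal["ner", "re", "nli"]
Role = Literal["label", "explain"]

ROLES: tuple[Role, Role] = ("label", "explain")


class ValidationError(ValueError):
    """Raised when an example or task specification violates an invariant."""


# ---------------------------------------------------------------------------
# Task specification and registry


@dataclass(frozen=True)
class TaskSpec:
    """One task: its prefix name, kind, category set C, and entity types.

    ``name`` doubles as the task prefix; ``label_set`` is the ordered,
    duplicate-free category set.  NER tasks additionally carry the entity
    type inventory (span types are the labels for NER).
    """

    name: str
    kind: TaskKind
    label_set: tuple[str, ...]
    entity_types: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if ":" in self.name or not self.name:
            raise ValidationError(f"task name {self.name!r} must be non-empty and contain no ':'")
        if self.kind not in ("ner", "re", "nli"):
            raise ValidationError(f"unknown task kind {self.kind!r}")
        object.__setattr__(self, "label_set", tuple(self.label_set))
        object.__setattr__(self, "entity_types", tuple(self.entity_types))
        if not self.label_set:
            raise ValidationError(f"task {self.name}: label_set is empty")
        if len(set(self.label_set)) != len(self.label_set):
            raise ValidationError(f"task {self.name}: label_set has duplicates")
        if self.kind == "ner":
            if not self.entity_types:
                raise ValidationError(f"ner task {self.name}: entity_types is empty")
            for t in self.entity_types:
                if not re.fullmatch(r"[a-z][a-z0-9_]*", t):
                    raise ValidationError(
                        f"ner task {self.name}: entity type {t!r} must be a lowercase identifier"
                    )


def write_task_registry(tasks: Sequence[TaskSpec], path: str | Path) -> None:
    payload = [
        {
            "name": t.name,
            "kind": t.kind,
            "label_set": list(t.label_set),
            "entity_types": list(t.entity_types),
        }
        for t in tasks
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_task_registry(path: str | Path) -> list[TaskSpec]:
    raw = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        TaskSpec(
            name=obj["name"],
            kind=obj["kind"],
            label_set=tuple(obj["label_set"]),
            entity_types=tuple(obj.get("entity_types", ())),
        )
        for obj in raw
    ]


# ---------------------------------------------------------------------------
# Examples, explanations, predictions


@dataclass(frozen=True)
class Span:
    """A typed entity span with 0-based half-open character offsets."""

    start: int
    end: int
    type: str
    surface: str


@dataclass(frozen=True)
class LabeledExample:
    """One training/evaluation item (x_i, y_i) for any task kind.

    NER items carry ``spans`` (their types are the labels; ``label`` is
    unused).  RE items carry ``label``; NLI items carry ``premise``,
    ``hypothesis`` and ``label``; ``text`` holds the packed pair string
    for NLI so every kind exposes a flat sentence.
    """

    id: str
    task: str
    text: str
    label: str = ""
    spans: tuple[Span, ...] = ()
    premise: str = ""
    hypothesis: str = ""


@dataclass(frozen=True)
class Explanation:
    """A reasoning chain r_i attached to an example by id.

    ``asserted_label`` is the label named in the chain's final assertion
    sentence, when one could be parsed.  ``source`` records provenance:
    a manually written demonstration, an LLM generation, or the mock LLM.
    """

    example_id: str
    text: str
    asserted_label: str | None = None
    source: Literal["manual", "llm", "mock"] = "llm"

    def __post_init__(self) -> None:
        if not self.text:
            raise ValidationError(f"explanation for {self.example_id}: text is empty")


@dataclass
class Prediction:
    """Raw generations for one query item plus their decoded forms."""

    example_id: str
    generated_label_text: str = ""
    generated_explanation_text: str = ""
    decoded_spans: list[tuple[str, str, int]] = field(default_factory=list)
    decoded_label: str | None = None
    error: str | None = None


# ---------------------------------------------------------------------------
# Validation and JSONL I/O

_MARKER_RE_CACHE: dict[tuple[str, ...], re.Pattern[str]] = {}


def _marker_tokens(entity_types: Sequence[str]) -> list[str]:
    toks = []
    for t in entity_types:
        toks.append(f"{t}*")
        toks.append(f"*{t}")
    return toks


def validate_example(ex: LabeledExample, task: TaskSpec) -> None:
    """Check every LabeledExample invariant; raise ValidationError naming the id."""
    if ex.task != task.name:
        raise ValidationError(f"example {ex.id}: task {ex.task!r} != spec {task.name!r}")
    if task.kind == "ner":
        prev_end = -1
        for sp in ex.spans:
            if not (0 <= sp.start < sp.end <= len(ex.text)):
                raise ValidationError(f"example {ex.id}: span offsets ({sp.start},{sp.end}) out of range")
            if sp.start < prev_end:
                raise ValidationError(f"example {ex.id}: spans overlap or are unsorted")
            prev_end = sp.end
            if ex.text[sp.start : sp.end] != sp.surface:
                raise ValidationError(
                    f"example {ex.id}: surface {sp.surface!r} != text[{sp.start}:{sp.end}] "
                    f"({ex.text[sp.start:sp.end]!r})"
                )
            if sp.type not in task.entity_types:
                raise ValidationError(f"example {ex.id}: unknown entity type {sp.type!r}")
        # marker-collision rule: raw text containing a marker token breaks
        # round-trip soundness, so such examples are rejected at load time
        for tok in _marker_tokens(task.entity_types):
            if tok in ex.text:
                raise ValidationError(f"example {ex.id}: text contains marker token {tok!r}")
    else:
        if ex.label not in task.label_set:
            raise ValidationError(f"example {ex.id}: label {ex.label!r} not in label_set of {task.name}")
        if task.kind == "nli" and not (ex.premise and ex.hypothesis):
            raise ValidationError(f"example {ex.id}: nli item missing premise or hypothesis")


def _example_from_obj(obj: dict, task: TaskSpec) -> LabeledExample:
    common = {"id": obj["id"], "task": obj["task"], "text": obj.get("text", "")}
    if task.kind == "ner":
        spans = tuple(
            Span(start=s["start"], end=s["end"], type=s["type"], surface=s["surface"])
            for s in obj.get("spans", ())
        )
        return LabeledExample(**common, spans=spans)
    if task.kind == "re":
        return LabeledExample(**common, label=obj["label"])
    ex = LabeledExample(
        **common,
        label=obj["label"],
        premise=obj["premise"],
        hypothesis=obj["hypothesis"],
    )
    if not ex.text:
        ex = LabeledExample(
            id=ex.id, task=ex.task, text=pack_nli(ex.premise, ex.hypothesis),
            label=ex.label, premise=ex.premise, hypothesis=ex.hypothesis,
        )
    return ex


def read_jsonl(path: str | Path, task: TaskSpec) -> list[LabeledExample]:
    """Load and validate a JSONL corpus for one task.

    Malformed JSON raises with the 1-based line number; invariant
    violations raise naming the offending example id.
    """
    out: list[LabeledExample] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            try:
                ex = _example_from_obj(obj, task)
            except KeyError as exc:
                raise ValidationError(f"{path} line {lineno}: missing field {exc}") from exc
            validate_example(ex, task)
            out.append(ex)
    return out


def example_to_obj(ex: LabeledExample, task: TaskSpec) -> dict:
    obj: dict = {"id": ex.id, "task": ex.task, "text": ex.text}
    if task.kind == "ner":
        obj["spans"] = [
            {"start": s.start, "end": s.end, "type": s.type, "surface": s.surface} for s in ex.spans
        ]
    elif task.kind == "re":
        obj["label"] = ex.label
    else:
        obj.update({"premise": ex.premise, "hypothesis": ex.hypothesis, "label": ex.label})
    return obj


def write_jsonl(examples: Iterable[LabeledExample], task: TaskSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(json.dumps(example_to_obj(ex, task), ensure_ascii=False) + "\n")


def write_explanations(explanations: Iterable[Explanation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in explanations:
            fh.write(json.dumps({
                "example_id": g.example_id, "text": g.text,
                "asserted_label": g.asserted_label, "source": g.source,
            }, ensure_ascii=False) + "\n")


def read_explanations(path: str | Path) -> list[Explanation]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValidationError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            out.append(Explanation(
                example_id=obj["example_id"], text=obj["text"],
                asserted_label=obj.get("asserted_label"), source=obj.get("source", "llm"),
            ))
    return out


# ---------------------------------------------------------------------------
# Codecs: examples -> text-to-text instances -> structured predictions


def pack_nli(premise: str, hypothesis: str) -> str:
    """Pack a premise-hypothesis pair into one flat input sequence."""
    return f"premise: {premise} hypothesis: {hypothesis}"


def encode_input(ex: LabeledExample, task: TaskSpec, role: Role) -> str:
    """Render the prefixed model input for one example and role.

    ``"<task>: <body>"`` routes label prediction, ``"explain <task>: <body>"``
    routes explanation generation; the body is the sentence (NER/RE) or the
    packed premise-hypothesis pair (NLI).
    """
    if ex.task != task.name:
        raise ValidationError(f"example {ex.id}: task {ex.task!r} != spec {task.name!r}")
    body = pack_nli(ex.premise, ex.hypothesis) if task.kind == "nli" else ex.text
    prefix = f"explain {task.name}: " if role == "explain" else f"{task.name}: "
    return prefix + body


def encode_ner_target(ex: LabeledExample, task: TaskSpec) -> str:
    """Serialize a NER example by wrapping each span as ``type* surface *type``.

    Spans are rewritten in place, left to right; all other characters are
    preserved verbatim, so a sentence without entities encodes to itself.
    """
    parts: list[str] = []
    cursor = 0
    for sp in ex.spans:
        if sp.start < cursor:
            raise ValidationError(f"example {ex.id}: overlapping spans")
        parts.append(ex.text[cursor : sp.start])
        parts.append(f"{sp.type}* {sp.surface} *{sp.type}")
        cursor = sp.end
    parts.append(ex.text[cursor:])
    return "".join(parts)


def decode_ner(generated: str, task: TaskSpec) -> list[tuple[str, str, int]]:
    """Extract every well-formed ``type* ... *type`` region from a generation.

    Returns ``(type, surface, occurrence_index)`` triples in reading order;
    the occurrence index distinguishes repeats of the same (type, surface).
    Unbalanced or crossed markers are skipped silently — decoding never
    raises, whatever the input.
    """
    key = task.entity_types
    pat = _MARKER_RE_CACHE.get(key)
    if pat is None:
        alts = "|".join(re.escape(t) for t in key)
        # shortest region per opener; opener and closer must carry the same type
        pat = re.compile(rf"(?P<t>{alts})\* (.*?) \*(?P=t)")
        _MARKER_RE_CACHE[key] = pat
    seen: dict[tuple[str, str], int] = {}
    out: list[tuple[str, str, int]] = []
    for m in pat.finditer(generated):
        etype, surface = m.group("t"), m.group(2)
        idx = seen.get((etype, surface), 0)
        seen[(etype, surface)] = idx + 1
        out.append((etype, surface, idx))
    return out


def ner_markers_balanced(generated: str, task: TaskSpec) -> bool:
    """True iff every marker token in the string belongs to a well-formed region."""
    key = task.entity_types
    pat = _MARKER_RE_CACHE.get(key)
    decode_ner(generated, task)  # ensure pattern cached
    pat = _MARKER_RE_CACHE[key]
    residue = pat.sub("", generated)
    return not any(tok in residue for tok in _marker_tokens(task.entity_types))


def encode_target(
    ex: LabeledExample,
    task: TaskSpec,
    role: Role,
    expl: Explanation | None = None,
) -> str:
    """Render the supervision target for one example and role.

    Label role: the marker-serialized sentence (NER) or the label verbatim
    (RE/NLI).  Explain role: ``"<label> explanation: <reasoning>"`` where
    the reasoning text ends with its own assertion sentence.
    """
    label_target = encode_ner_target(ex, task) if task.kind == "ner" else ex.label
    if role == "label":
        return label_target
    if expl is None:
        raise ValidationError(f"example {ex.id}: explain target requires an explanation")
    head = ex.label if task.kind != "ner" else "entities"
    return f"{head} explanation: {expl.text}"


def normalize_label(raw: str) -> str:
    """Normalize a generated label: first line only, stripped, casefolded."""
    first = raw.strip().splitlines()[0] if raw.strip() else ""
    return first.strip().strip(".").strip().casefold()


def decode_label(generated: str, task: TaskSpec) -> str | None:
    """Map a raw label-role generation to a member of the label set, if any."""
    norm = normalize_label(generated)
    for lab in task.label_set:
        if lab.casefold() == norm:
            return lab
    return None
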