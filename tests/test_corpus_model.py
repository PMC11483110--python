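"""Codec and I/O behaviour: serialization is exact, decoding is total."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from letex.corpus_model import (
    Explanation,
    LabeledExample,
    Span,
    TaskSpec,
    ValidationError,
    decode_label,
    decode_ner,
    encode_input,
    encode_ner_target,
    encode_target,
    ner_markers_balanced,
    read_jsonl,
    write_jsonl,
)


class TestTaskSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(name="a:b", kind="re", label_set=("x", "y")),
            dict(name="t", kind="re", label_set=()),
            dict(name="t", kind="re", label_set=("x", "x")),
            dict(name="t", kind="ner", label_set=("x",), entity_types=()),
            dict(name="t", kind="ner", label_set=("x",), entity_types=("Bad Type",)),
        ],
    )
    def test_invariant_violations_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            TaskSpec(**kwargs)


class TestJsonl:
    def _write(self, tmp_path, lines):
        p = tmp_path / "data.jsonl"
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return p

    def test_valid_ner_lines_load_identically(self, tmp_path, disease_task):
        rows = [
            {"id": f"e{i}", "task": "ncbi", "text": "flu in cohort",
             "spans": [{"start": 0, "end": 3, "type": "disease", "surface": "flu"}]}
            for i in range(3)
        ]
        loaded = read_jsonl(self._write(tmp_path, [json.dumps(r) for r in rows]), disease_task)
        assert len(loaded) == 3
        assert loaded[0].spans[0].surface == "flu"

    def test_surface_text_mismatch_names_example(self, tmp_path, disease_task):
        row = {"id": "bad-7", "task": "ncbi", "text": "flu in cohort",
               "spans": [{"start": 0, "end": 3, "type": "disease", "surface": "cold"}]}
        with pytest.raises(ValidationError, match="bad-7"):
            read_jsonl(self._write(tmp_path, [json.dumps(row)]), disease_task)

    def test_empty_file_gives_empty_list(self, tmp_path, disease_task):
        p = tmp_path / "empty.jsonl"
        p.write_text("")
        assert read_jsonl(p, disease_task) == []

    def test_malformed_json_names_line_number(self, tmp_path, disease_task):
        good = json.dumps({"id": "e0", "task": "ncbi", "text": "x", "spans": []})
        with pytest.raises(ValidationError, match="line 2"):
            read_jsonl(self._write(tmp_path, [good, "{not json"]), disease_task)

    def test_marker_collision_rejected_at_load(self, tmp_path, disease_task):
        row = {"id": "c0", "task": "ncbi", "text": "a disease* b", "spans": []}
        with pytest.raises(ValidationError, match="marker token"):
            read_jsonl(self._write(tmp_path, [json.dumps(row)]), disease_task)

    def test_write_read_round_trip(self, tmp_path, corpus, tasks):
        for task in tasks:
            p = tmp_path / f"{task.name}.jsonl"
            write_jsonl(corpus.examples[task.name], task, p)
            assert read_jsonl(p, task) == corpus.examples[task.name]


class TestEncodeInput:
    def test_re_prefixes_match_convention(self, i2b2_task):
        ex = LabeledExample(
            id="x", task="i2b2",
            text="Basilar artery stenosis with recurrent syndrome.", label="PIP",
        )
        assert encode_input(ex, i2b2_task, "label") == (
            "i2b2: Basilar artery stenosis with recurrent syndrome."
        )
        assert encode_input(ex, i2b2_task, "explain") == (
            "explain i2b2: Basilar artery stenosis with recurrent syndrome."
        )

    def test_nli_packing(self):
        task = TaskSpec(name="mednli", kind="nli", label_set=("entailment", "contradiction"))
        ex = LabeledExample(
            id="x", task="mednli", text="premise: A hypothesis: B",
            label="entailment", premise="A", hypothesis="B",
        )
        assert encode_input(ex, task, "label") == "mednli: premise: A hypothesis: B"

    def test_explain_prefix_bijection(self, corpus, tasks):
        for task in tasks:
            for ex in corpus.examples[task.name][:20]:
                assert encode_input(ex, task, "explain") == "explain " + encode_input(ex, task, "label")


def brute_force_ner_target(ex: LabeledExample) -> str:
    """Independent oracle: character-by-character insertion over offsets."""
    out = []
    opens = {sp.start: sp for sp in ex.spans}
    closes = {sp.end: sp for sp in ex.spans}
    for i, ch in enumerate(ex.text):
        if i in closes:
            out.append(f" *{closes[i].type}")
        if i in opens:
            out.append(f"{opens[i].type}* ")
        out.append(ch)
    if len(ex.text) in closes:
        out.append(f" *{closes[len(ex.text)].type}")
    return "".join(out)


class TestNerTarget:
    def test_single_disease_span_serialization(self, disease_example, disease_task):
        assert encode_ner_target(disease_example, disease_task) == (
            "Genotype and phenotype in patients with "
            "disease* dihydropyrimidine dehydrogenase deficiency *disease"
        )

    def test_zero_spans_is_identity(self, disease_task):
        ex = LabeledExample(id="z", task="ncbi", text="No findings at all.")
        assert encode_ner_target(ex, disease_task) == "No findings at all."

    def test_two_adjacent_spans(self):
        task = TaskSpec(name="g", kind="ner", label_set=("gene",), entity_types=("gene",))
        ex = LabeledExample(
            id="t", task="g", text="A B C",
            spans=(Span(0, 1, "gene", "A"), Span(4, 5, "gene", "C")),
        )
        assert encode_ner_target(ex, task) == "gene* A *gene B gene* C *gene"

    def test_matches_brute_force_insertion_oracle(self, corpus, ner_task):
        for ex in corpus.examples[ner_task.name]:
            assert encode_ner_target(ex, ner_task) == brute_force_ner_target(ex)


def scanner_decode(text: str, entity_types) -> list[tuple[str, str, int]]:
    """Regex-free oracle: scan for the earliest opener, then its closer."""
    found = []
    i = 0
    while i < len(text):
        best = None
        for t in entity_types:
            j = text.find(f"{t}* ", i)
            if j >= 0 and (best is None or j < best[0]):
                best = (j, t)
        if best is None:
            break
        j, t = best
        k = text.find(f" *{t}", j + len(t) + 2)
        if k < 0:
            i = j + 1
            continue
        # reject crossed regions: another opener of the same type inside
        inner = text[j + len(t) + 2 : k]
        found.append((t, inner))
        i = k + len(t) + 2
    seen = {}
    out = []
    for t, s in found:
        idx = seen.get((t, s), 0)
        seen[(t, s)] = idx + 1
        out.append((t, s, idx))
    return out


class TestDecodeNer:
    def test_decodes_single_span_target(self, disease_task):
        s = ("Genotype and phenotype in patients with "
             "disease* dihydropyrimidine dehydrogenase deficiency *disease")
        assert decode_ner(s, disease_task) == [
            ("disease", "dihydropyrimidine dehydrogenase deficiency", 0)
        ]

    def test_no_markers_gives_empty(self, disease_task):
        assert decode_ner("no markers here", disease_task) == []

    def test_occurrence_index_counts_repeats(self, disease_task):
        s = "disease* a *disease x disease* a *disease"
        assert decode_ner(s, disease_task) == [("disease", "a", 0), ("disease", "a", 1)]

    def test_round_trip_recovers_span_multiset(self, corpus, ner_task):
        for ex in corpus.examples[ner_task.name]:
            decoded = decode_ner(encode_ner_target(ex, ner_task), ner_task)
            assert sorted((t, s) for t, s, _ in decoded) == sorted(
                (sp.type, sp.surface) for sp in ex.spans
            )

    def test_totality_on_random_marker_alphabet_strings(self, ner_task):
        rng = np.random.default_rng(99)
        alphabet = ["disease*", "*disease", "gene*", "*gene", " ", "a", "b", "*"]
        for _ in range(10_000):
            n = int(rng.integers(0, 12))
            s = "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), n))
            spans = decode_ner(s, ner_task)  # must never raise
            assert isinstance(spans, list)
            ner_markers_balanced(s, ner_task)

    @given(st.text(alphabet=list("disease*gn xy"), max_size=80))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_decoding_is_total_on_adversarial_text(self, s):
        task = TaskSpec(name="t", kind="ner", label_set=("disease", "gene"),
                        entity_types=("disease", "gene"))
        spans = decode_ner(s, task)
        assert all(t in task.entity_types for t, _, _ in spans)
        assert isinstance(ner_markers_balanced(s, task), bool)

    def test_agrees_with_scanner_oracle_on_clean_targets(self, corpus, ner_task):
        for ex in corpus.examples[ner_task.name]:
            target = encode_ner_target(ex, ner_task)
            assert decode_ner(target, ner_task) == scanner_decode(target, ner_task.entity_types)


class TestEncodeTarget:
    def test_re_label_target_is_verbatim(self, i2b2_task):
        ex = LabeledExample(id="x", task="i2b2", text="...", label="PIP")
        assert encode_target(ex, i2b2_task, "label") == "PIP"

    def test_re_explain_target_carries_label_and_assertion(self, i2b2_task):
        ex = LabeledExample(id="x", task="i2b2", text="...", label="PIP")
        expl = Explanation(
            example_id="x",
            text="The medical problem of basilar stenosis causes thrombosis. So the label is PIP.",
        )
        target = encode_target(ex, i2b2_task, "explain", expl)
        assert target.startswith("PIP explanation: The medical problem of")
        assert target.endswith("So the label is PIP.")

    def test_nli_label_target(self, nli_task, corpus):
        ex = corpus.examples[nli_task.name][0]
        assert encode_target(ex, nli_task, "label") == ex.label

    def test_missing_explanation_errors(self, i2b2_task):
        ex = LabeledExample(id="x", task="i2b2", text="...", label="PIP")
        with pytest.raises(ValidationError):
            encode_target(ex, i2b2_task, "explain", None)


class TestDecodeLabel:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("PIP", "PIP"),
            ("  pip \n extra trailing line", "PIP"),
            ("TrAP.", "TrAP"),
            ("not-a-label", None),
            ("", None),
        ],
    )
    def test_normalization(self, i2b2_task, raw, expected):
        assert decode_label(raw, i2b2_task) == expected
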