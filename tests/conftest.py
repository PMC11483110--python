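import pytest

from letex.corpus_model import Explanation, LabeledExample, Span, TaskSpec
from letex.synth import SynthConfig, default_tasks, make_corpus


@pytest.fixture(scope="session")
def tasks():
    return default_tasks()


@pytest.fixture(scope="session")
def ner_task(tasks):
    return tasks[0]


@pytest.fixture(scope="session")
def re_task(tasks):
    return tasks[1]


@pytest.fixture(scope="session")
def nli_task(tasks):
    return tasks[2]


@pytest.fixture(scope="session")
def corpus(tasks):
    """A mid-sized synthetic corpus shared by read-only tests."""
    return make_corpus(SynthConfig(tasks=tasks, n_per_task=120, hallucination_rate=0.2, seed=7))


@pytest.fixture
def i2b2_task():
    """The clinical relation-extraction label set used in worked examples."""
    return TaskSpec(
        name="i2b2", kind="re",
        label_set=("TrIP", "TrWP", "TrCP", "TrAP", "TrNAP", "TeRP", "TeCP", "PIP"),
    )


@pytest.fixture
def disease_example():
    text = "Genotype and phenotype in patients with dihydropyrimidine dehydrogenase deficiency"
    surface = "dihydropyrimidine dehydrogenase deficiency"
    start = text.index(surface)
    return LabeledExample(
        id="ncbi-0", task="ncbi", text=text,
        spans=(Span(start=start, end=start + len(surface), type="disease", surface=surface),),
    )


@pytest.fixture
def disease_task():
    return TaskSpec(name="ncbi", kind="ner", label_set=("disease",), entity_types=("disease",))


@pytest.fixture
def gold_expl():
    def make(example_id, label, source="manual"):
        return Explanation(
            example_id=example_id,
            text=f"The decisive cue points at {label}. So the label is {label}.",
            asserted_label=label,
            source=source,
        )

    return make
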