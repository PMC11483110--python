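"""End-to-end orchestration of the explanation-learning pipeline.

Glue used by the command-line interface, the smoke tests, and the
results-reproduction script: synthesize corpora, collect mock-LLM
explanations, filter them, draw K-shot splits, train the multi-task
backbone on all tasks at once, and evaluate every query set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .collect import CollectResult, TrigramEmbedder, build_demo_pool, collect_explanations
from .corpus_model import TaskSpec
from .evaluation import TaskReport, evaluate_task
from .fewshot import QuerySet, SupportSet, sample_support
from .filtering import FilterResult, filter_dataset
from .multitask_train import (
    Backbone,
    LossBreakdown,
    Seq2SeqInstance,
    TrainConfig,
    build_instances,
    make_backbone,
    train,
)
from .synth import MockLLMClient, SynthConfig, SynthCorpus, default_tasks, make_corpus


@dataclass
class PipelineConfig:
    seed: int = 0
    n_per_task: int = 150
    hallucination_rate: float = 0.2
    n_demos: int = 20
    filter_threshold: float = 0.9
    filter_iters: int = 3
    K: int = 16
    epochs: int = 20
    lambda_weight: float = 0.5


@dataclass
class PipelineResult:
    corpus: SynthCorpus
    collected: dict[str, CollectResult]
    filtered: dict[str, FilterResult]
    supports: dict[str, SupportSet]
    queries: dict[str, QuerySet]
    instances: list[Seq2SeqInstance]
    backbone: Backbone
    history: list[LossBreakdown]
    reports: dict[str, TaskReport] = field(default_factory=dict)


def run_pipeline(cfg: PipelineConfig, tasks: tuple[TaskSpec, ...] | None = None) -> PipelineResult:
    """Run synth -> collect(mock) -> filter -> sample -> train -> eval."""
    tasks = tasks or default_tasks()
    corpus = make_corpus(SynthConfig(
        tasks=tasks, n_per_task=cfg.n_per_task,
        hallucination_rate=cfg.hallucination_rate, seed=cfg.seed,
    ))
    embedder = TrigramEmbedder()
    collected: dict[str, CollectResult] = {}
    filtered: dict[str, FilterResult] = {}
    supports: dict[str, SupportSet] = {}
    queries: dict[str, QuerySet] = {}
    for task in tasks:
        examples = corpus.examples[task.name]
        manual = {ex.id: corpus.gold_explanations[ex.id] for ex in examples}
        pool = build_demo_pool(examples, manual, task, n_demos=cfg.n_demos, seed=cfg.seed)
        client = MockLLMClient(task.label_set, cfg.hallucination_rate, seed=cfg.seed)
        res = collect_explanations(examples, pool, client, task, embedder)
        collected[task.name] = res
        collected_ids = [ex.id for ex, _ in res.explanations]
        filt = filter_dataset(
            [ex for ex, _ in res.explanations],
            [expl for _, expl in res.explanations],
            task,
            manual_seeds=[(d.example, d.explanation) for d in pool],
            threshold=cfg.filter_threshold,
            iters=cfg.filter_iters,
            seed=cfg.seed,
        )
        filtered[task.name] = filt
        support, query = sample_support(filt.retained, task, cfg.K, seed=cfg.seed)
        supports[task.name] = support
        queries[task.name] = query

    train_cfg = TrainConfig(
        lambda_weight=cfg.lambda_weight, epochs=cfg.epochs, seed=cfg.seed
    )
    instances: list[Seq2SeqInstance] = []
    for task in tasks:
        instances.extend(build_instances(supports[task.name], task))
    backbone = make_backbone(train_cfg)
    backbone, history = train(backbone, instances, train_cfg)

    result = PipelineResult(
        corpus=corpus, collected=collected, filtered=filtered,
        supports=supports, queries=queries, instances=instances,
        backbone=backbone, history=history,
    )
    for task in tasks:
        result.reports[task.name] = evaluate_task(backbone, queries[task.name], task)
    return result
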