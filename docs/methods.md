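# Methods

This note records the modeling choices behind `letex`, the parameters
that matter, what the synthetic study conditions do and do not emulate,
and the known limitations.

## Task serialization

All three task kinds are handled by one generative model through a
prefix convention: `"<task>: <body>"` requests the label, and
`"explain <task>: <body>"` requests the explanation, where `<task>` is
the dataset/task name. Targets:

- **NER** — the sentence with each entity span rewritten in place as
  `type* surface *type` (e.g. `disease* pleximia *disease`), left to
  right. Types are lowercase identifiers. A sentence that already
  contains a marker token is rejected at load time rather than escaped:
  round-trip soundness (decode(encode(x)) recovers the exact span
  multiset) is worth more here than accepting a pathological input.
  Decoded spans are matched at (type, surface, occurrence-index)
  granularity, since generation does not preserve character offsets;
  offsets can be recovered afterwards by sequential left-to-right
  search when needed. Nested and discontinuous entities, and token-level
  BIO schemes, are out of scope.
- **RE/NLI** — the label verbatim. NLI inputs pack the sentence pair as
  `premise: <p> hypothesis: <h>`; the explicit field names make the
  packing unambiguous and give a small model stable anchors.
- **Explain role** — `"<label> explanation: <reasoning>"`, the reasoning
  ending with the assertion sentence `So the label is <label>.` (for NER
  the target head is the literal word `entities`, since span types carry
  the labels).

Decoding is **total**: any string, however malformed, decodes to a
(possibly empty) structured prediction. Unbalanced or crossed markers
are skipped; generated labels are normalized (first line, whitespace and
trailing period stripped, case-insensitive) before matching against the
label set.

## Explanation collection

The demonstration pool is a uniform sample (default 20) of training
examples with manually written explanations. One demonstration is chosen
per query — k-NN with k = 1 — by cosine similarity of L2-normalized
character-3-gram count vectors (dimension 2048, hashed). This embedder
is deterministic and dependency-free; any `text -> vector` callable can
replace it. The prompt conditions the model on the query's gold label as
well as its text, which anchors the explanation to the correct label
rather than asking the model to solve the task. The prompt template is
an ordinary module-level string constant and is a `template=` parameter
everywhere, so it can be swapped without code changes. Client failures
are retried (default 2) and then recorded in a skip list; a batch never
aborts.

## Filtering and self-training

An explanation is trusted when the input text entails it, so vetting is
two-way NLI over (premise = input text, hypothesis = explanation).
Deterministic weak labels seed the discriminator:

- asserted label ≠ gold, or no label parseable → **contradiction**
  (treating unparseable assertions as contradictions is deliberate: an
  explanation that never states its label cannot supervise label
  generation);
- manual demonstration explanations → **entailment**.

For NER sentences, whose labels live on spans, the "gold label" of an
explanation is the type of the sentence's first span (first registered
type for entity-free sentences).

Explanations whose assertion *matches* gold are not auto-trusted; they
are the unlabeled candidates the discriminator must judge. Self-training
runs for `iters` iterations (default 3): candidates predicted entailment
with confidence ≥ `threshold` (default 0.9, an absolute cutoff; a
`top_q` fraction-based alternative is available since the choice between
the two is genuinely open) are added as entailment and the model refit.
Only entailment predictions are ever added — contradictions beyond the
seed set are not used as negatives. The final model partitions the
candidates into retained and discarded; the audit log records per
example whether discarding was rule-based (`asserted-mismatch`) or
model-based (`discriminator`). If either seed class is empty (e.g. a
corpus with no evident errors), no discriminator can be trained and all
candidates pass on the weak-label rule alone; this is logged as
`no-discriminator`.

The reference discriminator is bag-of-words logistic regression
(balanced class weights, lbfgs, fixed seed). It is a contract: any
`fit`/`predict` pair returning (label, probability-of-predicted-label)
can stand in, including fine-tuned transformer NLI models.

## K-shot sampling

All categories are used (N = |C|). RE/NLI supports are exactly K
uniform draws per class. For NER, exact K-per-class is generally
infeasible, so: repeatedly add, among sentences containing the currently
most-deficient class, the one that reduces total remaining deficit most
(ties: class order in the label set, then the seeded permutation order);
then prune, in sentence-id order, any sentence whose removal keeps every
class ≥ K. The result can exceed N·K instances but is irredundant, and
on small instances it matches exhaustive minimum-cover search (verified
in tests over all 2^12 subsets of a 12-sentence toy; exact minimum cover
is NP-hard in general, which is why a greedy heuristic is used at all).
Shot grids (default 16/32/64) extend smaller supports into larger ones
so the splits nest; infeasible shot counts are skipped with a warning
record rather than an error. Query sets are the full remainder of the
pool, never a subsample.

## Joint training

Each support item contributes one label-role and one explain-role
instance. The objective is L = λ·L_label + (1−λ)·L_expl with per-role
**means** (not a pooled mean), so λ's meaning does not drift with role
imbalance; λ defaults to 0.5 (symmetric prior — there is no
evidence-based value to prefer, and it is a config field).

Batching is **role-stratified**: each optimizer step takes one chunk of
label instances and one chunk of explain instances (chunk size 16), each
role shuffled by its own seeded generator. This has a correctness
purpose beyond throughput: the label-role update sequence is then
independent of whether explain instances exist, so a λ = 1 run is
bit-identical — parameters, label-loss history, generations — to the
label-only ablation run, and the ablation comparison is exact rather
than statistical. A role weighted exactly zero contributes loss
bookkeeping but no gradient arithmetic. Histories log one record per
epoch (per-role means over the epoch's steps and their weighted total);
a non-finite loss aborts with a diagnostic.

### The reference backbone

A from-scratch numpy character-level encoder–decoder, sized for corpora
of a few hundred short instances:

- encoder: hashed character-trigram counts (dim 512, L2-normalized) →
  one tanh layer, hidden size 96;
- decoder at position t: softmax over a fixed printable-ASCII vocabulary
  from [hidden ; previous-char embedding (32) ; position embedding
  (32)], maximum length 320;
- Adam, learning rate 0.05, greedy decoding everywhere (determinism for
  testing and evaluation).

The fixed vocabulary is deliberate: building it from training data would
make model shape depend on which instances are present and break the
ablation identity above. All randomness flows from one constructor
seed.

**Known limitation:** the decoder conditions on the input only through
the 96-dim sentence encoding and has no copy/attention mechanism. It
learns label selection well (the templated RE/NLI query sets are solved
exactly in the 16-shot smoke configuration) and always emits well-formed
marker syntax, but it cannot reproduce the exact surface form of unseen
entity mentions, so span-level NER F1 on held-out sentences is ~0. This
is a property of the desk-scale backbone, not of the serialization or
training scheme; the end-to-end checks therefore assert loss reduction
and generation well-formedness, and treat per-task query metrics as
reported observables. A pretrained encoder–decoder behind the same
contract is the intended vehicle for real NER performance.

## Synthetic study conditions

The generator stands in for restricted/large benchmark corpora and
emulates their structure, not their content: short templated sentences;
a closed label set per task; 0–3 non-overlapping typed NER spans drawn
from type-specific invented lexicons; RE sentences whose connective
template determines the relation (treats / causes / no_relation); NLI
hypotheses produced by entailment-preserving or negating edits of the
premise; and 2–4-sentence templated gold explanations ending with the
assertion sentence. Defaults: 100–150 examples per task, hallucination
rate 0.2, one master seed with fixed per-task offset streams (task
content is independent of generation order).

The mock LLM asserts the gold label with probability 1−rate and a
uniformly wrong label otherwise, recording which examples were
corrupted. Faithful generations reuse the manual templates' grounding
sentence — imitating the demonstration style, as an in-context model
does — while hallucinated ones drift to a hedged wording with their own
marker tokens ("conceivably", "overlooking"). This makes the corpus
linearly separable for the discriminator **by construction**; passing
filtering tests here shows the machinery (weak labels, self-training
loop, thresholding, audit) is correct, not that a bag-of-words model
would separate faithful from confabulated GPT-level prose. Likewise the
deterministic label-from-template mapping means query metrics here say
nothing about real-corpus difficulty. What the synthetic conditions do
carry over: every interface, invariant, and bookkeeping path is the one
a real deployment would exercise.

## Numerical and degenerate-input conventions

- Seeds: every stochastic component takes an explicit integer seed;
  derived streams use fixed offsets under `numpy` `SeedSequence`.
  Identical seeds give byte-identical corpora and bit-identical
  training runs.
- k-NN ties break toward the lowest pool index; sampler ties toward
  label-set order then sentence id.
- F1 is defined 0 when P + R = 0; micro counts are pooled before any
  division. The RE negative class (`no_relation`-style labels) is
  excluded from micro-F1 by default and configurable, since conventions
  differ across corpora.
- The self-training threshold must lie in (0.5, 1]; τ = 1.0 is allowed
  and is a no-op boundary (logistic confidences never reach it), which
  is occasionally useful as a control.
- Empty query sets evaluate to accuracy 0 with n = 0 rather than
  raising; empty explanation texts are invalid everywhere.

## Problem sizes

Tests and the reproduction script run the pipeline at 150 examples per
task, 16-shot supports, 20 training epochs, and n = 500 / 20% planted
errors for the filtering study — sizes chosen so the whole study runs in
seconds on one CPU while every class and code path is exercised many
times over.
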