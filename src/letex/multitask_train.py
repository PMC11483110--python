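"""Joint label + explanation training of a text-to-text backbone.

Every support item yields two seq2seq instances: a label-role instance
(``"<task>: <text>"`` -> label target) and an explain-role instance
(``"explain <task>: <text>"`` -> ``"<label> explanation: <reasoning>"``).
Training minimizes the weighted objective

    L = lambda * L_label + (1 - lambda) * L_expl

where each component is the mean cross-entropy over that role's
instances.  Per-role means (rather than one pooled mean) keep lambda's
meaning independent of how many instances each role contributes.
lambda = 1 recovers the label-only ablation (training without
explanations) exactly: explanation gradients are then never applied.

The reference backbone is a deliberately small character-level
encoder-decoder implemented in numpy: the input string is encoded as a
hashed character-trigram vector passed through one tanh layer, and the
decoder predicts each target character from the encoding, the previous
character's embedding, and a position embedding, trained with Adam.
It is randomly initialized — no pretrained weights — and is sized for
corpora of a few hundred short instances; any model exposing the same
loss/step/generate contract (e.g. a pretrained T5-class checkpoint) can
replace it behind the trainer.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus_model import ROLES, Role, TaskSpec, ValidationError, encode_input, encode_target
from .fewshot import SupportSet


@dataclass(frozen=True)
class Seq2SeqInstance:
    """One (input string, target string, role) training unit."""

    input: str
    target: str
    role: Role
    example_id: str

    def __post_init__(self) -> None:
        starts_explain = self.input.startswith("explain ")
        if (self.role == "explain") != starts_explain:
            raise ValidationError(
                f"instance {self.example_id}: role {self.role!r} inconsistent with prefix"
            )


@dataclass(frozen=True)
class TrainConfig:
    lambda_weight: float = 0.5
    epochs: int = 20
    batch_size: int = 16  # per-role chunk size; 0 = full batch
    learning_rate: float = 0.05
    seed: int = 0
    backbone: str = "char-ed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_weight <= 1.0:
            raise ValidationError("lambda_weight must lie in [0, 1]")


@dataclass(frozen=True)
class LossBreakdown:
    """Per-step record of L_label, L_expl and their weighted total."""

    label_loss: float
    expl_loss: float
    total: float


@runtime_checkable
class Backbone(Protocol):
    """Contract a trainable text-to-text model must satisfy."""

    def loss(self, batch: Sequence[Seq2SeqInstance]) -> dict[str, float]: ...

    def step(self, batch: Sequence[Seq2SeqInstance], lambda_weight: float) -> dict[str, float]: ...

    def generate(self, input_text: str) -> str: ...


def build_instances(
    support: SupportSet, task: TaskSpec
) -> list[Seq2SeqInstance]:
    """Expand a support set into paired label/explain seq2seq instances."""
    out: list[Seq2SeqInstance] = []
    for ex, _, expl in support.items:
        if expl is None:
            raise ValidationError(f"support item {ex.id} lacks an explanation")
        for role in ROLES:
            out.append(
                Seq2SeqInstance(
                    input=encode_input(ex, task, role),
                    target=encode_target(ex, task, role, expl),
                    role=role,
                    example_id=ex.id,
                )
            )
    return out


def joint_loss(label_loss: float, expl_loss: float, lambda_weight: float) -> float:
    """The weighted objective L = lambda*L_label + (1-lambda)*L_expl."""
    if not 0.0 <= lambda_weight <= 1.0:
        raise ValidationError("lambda_weight must lie in [0, 1]")
    if label_loss < 0 or expl_loss < 0:
        raise ValidationError("cross-entropy losses must be non-negative")
    return lambda_weight * label_loss + (1.0 - lambda_weight) * expl_loss


# ---------------------------------------------------------------------------
# Reference backbone


_CHARSET = string.printable  # fixed vocabulary: independent of the corpus
_BOS, _EOS, _UNK = 0, 1, 2
_OFFSET = 3


def _hash_trigrams(text: str, dim: int) -> np.ndarray:
    v = np.zeros(dim, dtype=np.float64)
    padded = f"  {text} "
    for i in range(len(padded) - 2):
        v[zlib.crc32(padded[i : i + 3].encode("utf-8")) % dim] += 1.0
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


class CharSeq2Seq:
    """Reference character-level encoder-decoder trained from scratch.

    Encoder: L2-normalized hashed character-trigram counts of the input,
    through one tanh layer -> hidden state h.  Decoder, per position t:
    logits over the character vocabulary from [h ; emb(prev char) ;
    emb(t)].  Greedy decoding; Adam optimizer; all randomness flows from
    the constructor seed, so training and generation are reproducible
    bit for bit.
    """

    def __init__(
        self,
        seed: int = 0,
        feat_dim: int = 512,
        hidden: int = 96,
        char_dim: int = 32,
        pos_dim: int = 32,
        max_len: int = 320,
        learning_rate: float = 0.05,
    ) -> None:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
        self.vocab = {c: i + _OFFSET for i, c in enumerate(_CHARSET)}
        self.inv_vocab = {i: c for c, i in self.vocab.items()}
        V = _OFFSET + len(_CHARSET)
        self.V, self.H, self.D = V, hidden, feat_dim
        self.max_len = max_len
        self.lr = learning_rate
        ctx = hidden + char_dim + pos_dim
        s = 0.1
        self.params = {
            "W_e": rng.normal(0, s, (hidden, feat_dim)),
            "b_e": np.zeros(hidden),
            "E": rng.normal(0, s, (V, char_dim)),
            "P": rng.normal(0, s, (max_len, pos_dim)),
            "W_o": rng.normal(0, s, (V, ctx)),
            "b_o": np.zeros(V),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self._feat_cache: dict[str, np.ndarray] = {}

    # -- encoding helpers

    def _feat(self, text: str) -> np.ndarray:
        f = self._feat_cache.get(text)
        if f is None:
            f = _hash_trigrams(text, self.D)
            self._feat_cache[text] = f
        return f

    def _ids(self, text: str) -> list[int]:
        return [self.vocab.get(c, _UNK) for c in text[: self.max_len - 1]]

    # -- forward / backward for one instance

    def _forward(self, inst: Seq2SeqInstance):
        p = self.params
        f = self._feat(inst.input)
        pre = p["W_e"] @ f + p["b_e"]
        h = np.tanh(pre)
        tgt = self._ids(inst.target) + [_EOS]
        prev = np.array([_BOS] + tgt[:-1])
        T = len(tgt)
        pos = np.arange(T)
        ctxs = np.concatenate([np.tile(h, (T, 1)), p["E"][prev], p["P"][pos]], axis=1)
        logits = ctxs @ p["W_o"].T + p["b_o"]
        shifted = logits - logits.max(axis=1, keepdims=True)
        expv = np.exp(shifted)
        probs = expv / expv.sum(axis=1, keepdims=True)
        nll = -np.log(np.maximum(probs[np.arange(T), tgt], 1e-300))
        return float(nll.mean()), (f, h, prev, pos, np.asarray(tgt), ctxs, probs)

    def _backward(self, cache, grads: dict[str, np.ndarray]) -> None:
        p = self.params
        f, h, prev, pos, tgt, ctxs, probs = cache
        T = len(tgt)
        dlogits = probs.copy()
        dlogits[np.arange(T), tgt] -= 1.0
        dlogits /= T
        grads["W_o"] += dlogits.T @ ctxs
        grads["b_o"] += dlogits.sum(axis=0)
        dctx = dlogits @ p["W_o"]
        H = self.H
        dh = dctx[:, :H].sum(axis=0)
        np.add.at(grads["E"], prev, dctx[:, H : H + p["E"].shape[1]])
        np.add.at(grads["P"], pos, dctx[:, H + p["E"].shape[1] :])
        dpre = dh * (1.0 - h * h)
        grads["W_e"] += np.outer(dpre, f)
        grads["b_e"] += dpre

    # -- public contract

    def loss(self, batch: Sequence[Seq2SeqInstance]) -> dict[str, float]:
        """Mean cross-entropy per role over the batch (no update)."""
        sums = {"label": 0.0, "explain": 0.0}
        counts = {"label": 0, "explain": 0}
        for inst in batch:
            nll, _ = self._forward(inst)
            sums[inst.role] += nll
            counts[inst.role] += 1
        return {r: (sums[r] / counts[r] if counts[r] else 0.0) for r in sums}

    def step(self, batch: Sequence[Seq2SeqInstance], lambda_weight: float) -> dict[str, float]:
        """One Adam step on lambda*L_label + (1-lambda)*L_expl.

        Returns the pre-update per-role losses.  A role weighted by
        exactly zero contributes no gradient arithmetic at all, so a
        lambda=1 run updates parameters identically to a run that never
        saw the explain instances.
        """
        role_grads = {
            r: {k: np.zeros_like(v) for k, v in self.params.items()} for r in ROLES
        }
        sums = {"label": 0.0, "explain": 0.0}
        counts = {"label": 0, "explain": 0}
        weights = {"label": lambda_weight, "explain": 1.0 - lambda_weight}
        for inst in batch:
            if weights[inst.role] == 0.0:
                nll, _ = self._forward(inst)
            else:
                nll, cache = self._forward(inst)
                self._backward(cache, role_grads[inst.role])
            sums[inst.role] += nll
            counts[inst.role] += 1
        total_grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        for role in ROLES:
            w = weights[role]
            if w == 0.0 or counts[role] == 0:
                continue
            scale = w / counts[role]
            for k in total_grads:
                total_grads[k] += scale * role_grads[role][k]
        self._adam_update(total_grads)
        return {r: (sums[r] / counts[r] if counts[r] else 0.0) for r in sums}

    def _adam_update(self, grads, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * (g * g)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)

    def generate(self, input_text: str) -> str:
        """Greedy decode until EOS or the position limit."""
        p = self.params
        h = np.tanh(p["W_e"] @ self._feat(input_text) + p["b_e"])
        out: list[str] = []
        prev = _BOS
        for t in range(self.max_len):
            ctx = np.concatenate([h, p["E"][prev], p["P"][t]])
            logits = p["W_o"] @ ctx + p["b_o"]
            nxt = int(logits.argmax())
            if nxt == _EOS:
                break
            out.append(self.inv_vocab.get(nxt, ""))
            prev = nxt
        return "".join(out)

    def state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def make_backbone(cfg: TrainConfig) -> Backbone:
    if cfg.backbone != "char-ed":
        raise ValidationError(f"unknown backbone {cfg.backbone!r}")
    return CharSeq2Seq(seed=cfg.seed, learning_rate=cfg.learning_rate)


# ---------------------------------------------------------------------------
# Trainer


def train(
    backbone: Backbone,
    instances: Sequence[Seq2SeqInstance],
    cfg: TrainConfig,
) -> tuple[Backbone, list[LossBreakdown]]:
    """Fit the backbone with role-stratified mini-batches.

    Each optimizer step mixes one chunk of label-role instances with one
    chunk of explain-role instances; the two role streams are shuffled by
    independent generators derived from the seed.  Stratification keeps
    the label-role update sequence independent of whether explain
    instances exist at all, so a lambda=1 run reproduces the label-only
    ablation (training without explanations) exactly, update for update.

    The history logs one record per epoch: the per-role mean losses over
    that epoch's steps (measured before each update) and their
    lambda-weighted total.  An interior lambda requires both roles;
    the boundary values permit single-role instance lists.
    """
    if not instances:
        raise ValidationError("no training instances")
    roles = {inst.role for inst in instances}
    lam = cfg.lambda_weight
    if 0.0 < lam < 1.0 and roles != {"label", "explain"}:
        raise ValidationError(f"interior lambda={lam} requires both roles, got {roles}")
    by_role: dict[str, list[Seq2SeqInstance]] = {"label": [], "explain": []}
    for inst in instances:
        by_role[inst.role].append(inst)
    rngs = {
        role: np.random.default_rng(np.random.SeedSequence([cfg.seed, 31, i]))
        for i, role in enumerate(ROLES)
    }
    n_steps = max(
        _n_chunks(len(by_role[r]), cfg.batch_size) for r in ROLES if by_role[r]
    )
    history: list[LossBreakdown] = []
    for _ in range(cfg.epochs):
        chunks = {
            role: _chunked(by_role[role], cfg.batch_size, rngs[role], n_steps)
            for role in ROLES
        }
        sums = {"label": 0.0, "explain": 0.0}
        counts = {"label": 0, "explain": 0}
        for s in range(n_steps):
            batch = chunks["label"][s] + chunks["explain"][s]
            role_losses = backbone.step(batch, lam)
            for role in ROLES:
                if chunks[role][s]:
                    sums[role] += role_losses[role]
                    counts[role] += 1
        label_loss = sums["label"] / counts["label"] if counts["label"] else 0.0
        expl_loss = sums["explain"] / counts["explain"] if counts["explain"] else 0.0
        bd = LossBreakdown(
            label_loss=label_loss,
            expl_loss=expl_loss,
            total=joint_loss(label_loss, expl_loss, lam),
        )
        if not np.isfinite(bd.total):
            raise ValidationError(f"non-finite loss at epoch {len(history)}: {bd}")
        history.append(bd)
    return backbone, history


def _n_chunks(n: int, batch_size: int) -> int:
    if n == 0:
        return 0
    if batch_size <= 0:
        return 1
    return -(-n // batch_size)


def _chunked(
    items: list[Seq2SeqInstance],
    batch_size: int,
    rng: np.random.Generator,
    n_steps: int,
) -> list[list[Seq2SeqInstance]]:
    """Shuffle one role's instances and split them across the epoch's steps."""
    if not items:
        return [[] for _ in range(n_steps)]
    order = [items[int(i)] for i in rng.permutation(len(items))]
    size = len(order) if batch_size <= 0 else batch_size
    chunks = [order[i : i + size] for i in range(0, len(order), size)]
    while len(chunks) < n_steps:  # pad short role streams with empty chunks
        chunks.append([])
    return chunks[:n_steps]
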