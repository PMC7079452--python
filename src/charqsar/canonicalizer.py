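"""Sequence-to-sequence normalizer: arbitrary SMILES -> canonical SMILES.

Encoder-decoder Transformer (post-norm, sinusoidal positions, teacher
forcing, greedy decoding) implemented on the local autodiff core. The
encoder doubles as the embedding extractor for the QSAR stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .tokenizer_io import (PairRecord, Vocabulary, default_vocabulary,
                           tokenize)

logger = logging.getLogger(__name__)

__all__ = [
    "TransformerConfig", "LRSchedule", "TrainState", "Canonicalizer",
    "lr_at_step", "build_canonicalizer", "train_canonicalizer",
    "greedy_decode", "greedy_decode_batch", "canonicalization_report",
    "save_checkpoint", "load_checkpoint", "vocabulary_hash",
]

NEG_INF = -1e9


@dataclass(frozen=True)
class TransformerConfig:
    n_layers: int = 3
    n_heads: int = 8
    d_model: int = 64
    d_ff: int = 256
    dropout: float = 0.1
    max_len: int = 110
    norm_first: bool = False   # pre-norm residual blocks train more stably at small scale
    tie_weights: bool = False  # share token embedding with the output projection

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.max_len < 3:
            raise ValueError("max_len too small")


@dataclass(frozen=True)
class LRSchedule:
    """lambda(step) = max(floor, factor * min(1, step/warmup) / max(step, warmup))."""

    factor: float = 20.0
    warmup: int = 16000
    floor: float = 1e-4

    def __post_init__(self):
        if self.factor <= 0 or self.warmup <= 0 or self.floor <= 0:
            raise ValueError("schedule parameters must be positive")


def lr_at_step(step: int, sched: LRSchedule) -> float:
    if step < 1:
        raise ValueError("step must be >= 1")
    lam = sched.factor * min(1.0, step / sched.warmup) / max(step, sched.warmup)
    return max(sched.floor, lam)


@dataclass
class TrainState:
    step: int = 0
    epoch: int = 0
    char_accuracy: float = 0.0
    loss: float = float("nan")
    history: list = field(default_factory=list)


def sinusoidal_positions(max_len: int, d_model: int) -> np.ndarray:
    pos = np.arange(max_len)[:, None].astype(np.float64)
    dim = np.arange(d_model)[None, :].astype(np.float64)
    angle = pos / np.power(10000.0, (2 * (dim // 2)) / d_model)
    enc = np.zeros((max_len, d_model))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


class MultiHeadAttention(nn.Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        self.h = n_heads
        self.dk = d_model // n_heads
        self.wq = nn.Dense(d_model, d_model, rng)
        self.wk = nn.Dense(d_model, d_model, rng)
        self.wv = nn.Dense(d_model, d_model, rng)
        self.wo = nn.Dense(d_model, d_model, rng)

    def __call__(self, q_in: Tensor, kv_in: Tensor, mask: np.ndarray | None) -> Tensor:
        B, Tq, D = q_in.shape
        Tk = kv_in.shape[1]

        def split(x: Tensor, T: int) -> Tensor:
            return x.reshape(B, T, self.h, self.dk).transpose(0, 2, 1, 3)

        q = split(self.wq(q_in), Tq)
        k = split(self.wk(kv_in), Tk)
        v = split(self.wv(kv_in), Tk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dk))
        if mask is not None:
            scores = scores + Tensor(mask)          # additive, 0 or NEG_INF
        attn = scores.softmax(axis=-1)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, Tq, D)
        return self.wo(ctx)


class FeedForward(nn.Module):
    def __init__(self, d_model: int, d_ff: int, rng: np.random.Generator):
        self.lin1 = nn.Dense(d_model, d_ff, rng)
        self.lin2 = nn.Dense(d_ff, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.lin2(self.lin1(x).relu())


class EncoderLayer(nn.Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.norm_first = cfg.norm_first
        self.attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ffn = FeedForward(cfg.d_model, cfg.d_ff, rng)
        self.norm1 = nn.LayerNorm(cfg.d_model)
        self.norm2 = nn.LayerNorm(cfg.d_model)

    def __call__(self, x: Tensor, mask, drop) -> Tensor:
        if self.norm_first:
            y = self.norm1(x)
            x = x + drop(self.attn(y, y, mask))
            return x + drop(self.ffn(self.norm2(x)))
        x = self.norm1(x + drop(self.attn(x, x, mask)))
        return self.norm2(x + drop(self.ffn(x)))


class DecoderLayer(nn.Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        self.norm_first = cfg.norm_first
        self.self_attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.cross_attn = MultiHeadAttention(cfg.d_model, cfg.n_heads, rng)
        self.ffn = FeedForward(cfg.d_model, cfg.d_ff, rng)
        self.norm1 = nn.LayerNorm(cfg.d_model)
        self.norm2 = nn.LayerNorm(cfg.d_model)
        self.norm3 = nn.LayerNorm(cfg.d_model)

    def __call__(self, x: Tensor, memory: Tensor, self_mask, cross_mask, drop) -> Tensor:
        if self.norm_first:
            x = x + drop(self.self_attn(self.norm1(x), self.norm1(x), self_mask))
            x = x + drop(self.cross_attn(self.norm2(x), memory, cross_mask))
            return x + drop(self.ffn(self.norm3(x)))
        x = self.norm1(x + drop(self.self_attn(x, x, self_mask)))
        x = self.norm2(x + drop(self.cross_attn(x, memory, cross_mask)))
        return self.norm3(x + drop(self.ffn(x)))


class _TiedGenerator(nn.Module):
    """Output projection sharing the token-embedding matrix."""

    def __init__(self, embed: nn.Embedding, vocab_size: int):
        self._embed_ref = embed          # not a parameter of this module
        self.b = Tensor(np.zeros(vocab_size), requires_grad=True)

    def parameters(self):
        return [self.b]

    def state_arrays(self, prefix: str = ""):
        return {prefix + "b": self.b.data}

    def load_state_arrays(self, arrays, prefix: str = ""):
        self.b.data = np.asarray(arrays[prefix + "b"], dtype=np.float64)

    def __call__(self, x: Tensor) -> Tensor:
        w = self._embed_ref.w
        return x @ w.transpose(1, 0) + self.b


class Canonicalizer(nn.Module):
    """Encoder-decoder over character token ids."""

    def __init__(self, config: TransformerConfig, vocab: Vocabulary,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.vocab = vocab
        self.embed = nn.Embedding(vocab.size, config.d_model, rng)
        self.enc_layers = [EncoderLayer(config, rng) for _ in range(config.n_layers)]
        self.dec_layers = [DecoderLayer(config, rng) for _ in range(config.n_layers)]
        if config.tie_weights:
            self.generator = _TiedGenerator(self.embed, vocab.size)
        else:
            self.generator = nn.Dense(config.d_model, vocab.size, rng)
        self._pos = sinusoidal_positions(config.max_len + 2, config.d_model)
        self._scale = np.sqrt(config.d_model)

    # -- masks ---------------------------------------------------------
    def pad_mask(self, ids: np.ndarray) -> np.ndarray:
        """(B, 1, 1, Tk) additive mask hiding pad keys."""
        return np.where(ids == self.vocab.pad_id, NEG_INF, 0.0)[:, None, None, :]

    @staticmethod
    def causal_mask(T: int) -> np.ndarray:
        return np.where(np.triu(np.ones((T, T)), k=1) > 0, NEG_INF, 0.0)[None, None]

    # -- forward -------------------------------------------------------
    def _drop(self, rate: float, rng: np.random.Generator | None):
        if rng is None or rate <= 0:
            return lambda x: x
        return lambda x: x * Tensor(nn.dropout_mask(x.shape, rate, rng))

    def _embed(self, ids: np.ndarray) -> Tensor:
        T = ids.shape[1]
        return self.embed(ids) * self._scale + Tensor(self._pos[:T])

    def encode(self, src_ids: np.ndarray, train_rng=None) -> Tensor:
        drop = self._drop(self.config.dropout, train_rng)
        mask = self.pad_mask(src_ids)
        x = drop(self._embed(src_ids))
        for layer in self.enc_layers:
            x = layer(x, mask, drop)
        return x

    def decode(self, memory: Tensor, src_ids: np.ndarray, tgt_ids: np.ndarray,
               train_rng=None) -> Tensor:
        drop = self._drop(self.config.dropout, train_rng)
        T = tgt_ids.shape[1]
        self_mask = self.causal_mask(T) + np.where(
            tgt_ids == self.vocab.pad_id, NEG_INF, 0.0)[:, None, None, :]
        cross_mask = self.pad_mask(src_ids)
        x = drop(self._embed(tgt_ids))
        for layer in self.dec_layers:
            x = layer(x, memory, self_mask, cross_mask, drop)
        return self.generator(x)

    def forward(self, src_ids: np.ndarray, tgt_ids: np.ndarray,
                train_rng=None) -> Tensor:
        return self.decode(self.encode(src_ids, train_rng), src_ids, tgt_ids,
                           train_rng)


def build_canonicalizer(config: TransformerConfig,
                        vocab: Vocabulary | None = None,
                        seed: int = 0) -> Canonicalizer:
    return Canonicalizer(config, vocab or default_vocabulary(), seed=seed)


# -- training ----------------------------------------------------------

def _pad_batch(seqs: Sequence[Sequence[int]], pad_id: int) -> np.ndarray:
    T = max(len(s) for s in seqs)
    out = np.full((len(seqs), T), pad_id, dtype=np.int64)
    for i, s in enumerate(seqs):
        out[i, :len(s)] = s
    return out


def _batch_loss(model: Canonicalizer, src: np.ndarray, tgt: np.ndarray,
                train_rng=None, label_smoothing: float = 0.0):
    """Teacher-forced cross-entropy; returns (loss, n_correct, n_tokens)."""
    pad = model.vocab.pad_id
    tgt_in, tgt_out = tgt[:, :-1], tgt[:, 1:]
    logits = model.forward(src, tgt_in, train_rng)
    logp = logits.log_softmax(axis=-1)
    picked = logp.take_along_last(tgt_out)
    keep = (tgt_out != pad).astype(np.float64)
    n_tok = keep.sum()
    loss = -(picked.reshape(*tgt_out.shape) * Tensor(keep)).sum() * (1.0 / n_tok)
    if label_smoothing > 0:
        uniform = -(logp.mean(axis=-1) * Tensor(keep)).sum() * (1.0 / n_tok)
        loss = loss * (1.0 - label_smoothing) + uniform * label_smoothing
    pred = np.argmax(logits.data, axis=-1)
    n_correct = int(((pred == tgt_out) * keep).sum())
    return loss, n_correct, int(n_tok)


def train_canonicalizer(
    pairs: Sequence[PairRecord],
    config: TransformerConfig,
    sched: LRSchedule | None = None,
    epochs: int = 10,
    seed: int = 0,
    batch_size: int = 16,
    model: Canonicalizer | None = None,
    vocab: Vocabulary | None = None,
    clip_norm: float = 2.0,
    log_every: int = 50,
    label_smoothing: float = 0.0,
    adam_betas: tuple = (0.9, 0.999),
) -> tuple[Canonicalizer, TrainState]:
    """Next-token cross-entropy with the warmup/decay schedule.

    No early stopping or weight averaging at this stage; character
    accuracy on the training stream is logged as the progress metric.
    """
    if not pairs:
        raise ValueError("no training pairs")
    vocab = vocab or default_vocabulary()
    sched = sched or LRSchedule()
    if model is None:
        model = build_canonicalizer(config, vocab, seed=seed)
    rng = np.random.default_rng(seed + 1)
    drop_rng = np.random.default_rng(seed + 2)

    enc = [(tokenize(p.source, vocab).ids, tokenize(p.target, vocab).ids)
           for p in pairs]
    params = model.parameters()
    opt = nn.Adam(params, betas=adam_betas)
    state = TrainState()
    order = np.arange(len(enc))
    for epoch in range(epochs):
        rng.shuffle(order)
        correct = total = 0
        for lo in range(0, len(order), batch_size):
            idx = order[lo:lo + batch_size]
            src = _pad_batch([enc[i][0] for i in idx], vocab.pad_id)
            tgt = _pad_batch([enc[i][1] for i in idx], vocab.pad_id)
            loss, n_c, n_t = _batch_loss(
                model, src, tgt, drop_rng if config.dropout > 0 else None,
                label_smoothing=label_smoothing)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at step {state.step + 1} "
                    f"(epoch {epoch}, lr={opt.lr:.2e})")
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(params, clip_norm)
            state.step += 1
            opt.step(lr=lr_at_step(state.step, sched))
            correct += n_c
            total += n_t
            state.loss = float(loss.data)
            if state.step % log_every == 0:
                logger.info("step %d epoch %d loss %.4f acc %.3f lr %.2e",
                            state.step, epoch, state.loss,
                            correct / max(total, 1), opt.lr)
        state.epoch = epoch + 1
        state.char_accuracy = correct / max(total, 1)
        state.history.append({"epoch": epoch + 1, "loss": state.loss,
                              "char_accuracy": state.char_accuracy})
    return model, state


# -- decoding ----------------------------------------------------------

def greedy_decode_batch(model: Canonicalizer, smiles_list: Sequence[str],
                        max_len: int | None = None) -> list[str]:
    """Argmax decoding for a batch; stops each item at its end marker."""
    vocab = model.vocab
    max_len = max_len or model.config.max_len
    src = _pad_batch([tokenize(s, vocab).ids for s in smiles_list], vocab.pad_id)
    memory = model.encode(src)
    B = len(smiles_list)
    out_ids = np.full((B, 1), vocab.start_id, dtype=np.int64)
    done = np.zeros(B, dtype=bool)
    for _ in range(max_len + 1):
        logits = model.decode(memory, src, out_ids)
        nxt = np.argmax(logits.data[:, -1, :], axis=-1)
        nxt[done] = vocab.pad_id
        out_ids = np.concatenate([out_ids, nxt[:, None]], axis=1)
        done |= nxt == vocab.end_id
        if done.all():
            break
    results = []
    for b in range(B):
        chars = []
        for i in out_ids[b, 1:]:
            if i in (vocab.end_id, vocab.pad_id):
                break
            chars.append(vocab.symbols[i] if i < len(vocab.symbols) else "?")
        results.append("".join(chars))
    return results


def greedy_decode(model: Canonicalizer, smiles: str,
                  max_len: int | None = None) -> str:
    return greedy_decode_batch(model, [smiles], max_len)[0]


def canonicalization_report(model: Canonicalizer, smiles_list: Sequence[str],
                            oracle, batch_size: int = 64) -> dict:
    """Exact-match restoration rates, overall and for stereo / cis-trans
    subsets, plus the fraction of inputs that were already canonical."""
    if not smiles_list:
        raise ValueError("empty evaluation list")
    targets = [oracle.canonical(s) for s in smiles_list]
    decoded: list[str] = []
    for lo in range(0, len(smiles_list), batch_size):
        decoded.extend(greedy_decode_batch(model, smiles_list[lo:lo + batch_size]))
    hits = [d == t for d, t in zip(decoded, targets)]

    def rate(mask):
        n = sum(mask)
        k = sum(h for h, m in zip(hits, mask) if m)
        return {"n": n, "correct": k, "rate": k / n if n else float("nan")}

    stereo = [("@" in s) for s in smiles_list]
    cistrans = [("/" in s or "\\" in s) for s in smiles_list]
    return {
        "all": rate([True] * len(hits)),
        "stereo": rate(stereo),
        "cis_trans": rate(cistrans),
        "already_canonical_fraction":
            sum(s == t for s, t in zip(smiles_list, targets)) / len(smiles_list),
    }


# -- checkpointing -----------------------------------------------------

def vocabulary_hash(vocab: Vocabulary) -> str:
    return hashlib.sha256("".join(vocab.symbols).encode()).hexdigest()[:16]


def save_checkpoint(model: Canonicalizer, path, metadata: dict | None = None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state_arrays())
    sidecar = {
        "config": asdict(model.config),
        "vocab_hash": vocabulary_hash(model.vocab),
        "metadata": metadata or {},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path, vocab: Vocabulary | None = None) -> Canonicalizer:
    path = Path(path)
    vocab = vocab or default_vocabulary()
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar["vocab_hash"] != vocabulary_hash(vocab):
        raise ValueError("checkpoint was trained with a different vocabulary")
    config = TransformerConfig(**sidecar["config"])
    model = Canonicalizer(config, vocab)
    with np.load(path.with_suffix(".npz")) as arrays:
        model.load_state_arrays(dict(arrays))
    return model
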