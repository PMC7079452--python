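"""Convolutional QSAR head over frozen dynamic embeddings.

Per-kernel 1D convolutions -> ReLU -> global max-pool -> concat ->
dropout -> dense -> highway -> output (one neuron for regression, two
for classification). Inputs are always right-padded with at least one
full window of zeros beyond the largest kernel, which makes the pooled
features — and hence predictions — invariant to further padding.
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
from .canonicalizer import Canonicalizer, load_checkpoint, save_checkpoint
from .embedding import batch_extract
from .tokenizer_io import QsarRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CnnHeadConfig", "CnnHead", "QsarModel", "build_head", "train_qsar",
    "predict_raw", "predict_batch", "encoder_hash",
    "save_qsar_model", "load_qsar_model",
]

KERNEL_SIZES = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20)
FILTER_COUNTS = (100, 200, 200, 200, 200, 100, 100, 100, 100, 100, 160, 160)


@dataclass(frozen=True)
class CnnHeadConfig:
    kernel_sizes: tuple = KERNEL_SIZES
    filter_counts: tuple = FILTER_COUNTS
    dropout: float = 0.25
    dense_width: int = 512
    task: str = "regression"            # regression | classification
    learning_rate: float = 1e-4
    max_epochs: int = 100
    patience: int = 10
    holdout_fraction: float = 0.10
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if len(self.kernel_sizes) != len(self.filter_counts):
            raise ValueError("kernel_sizes and filter_counts must align")
        if self.task not in ("regression", "classification"):
            raise ValueError(f"unknown task {self.task!r}")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")

    @property
    def pooled_width(self) -> int:
        return int(sum(self.filter_counts))


class CnnHead(nn.Module):
    def __init__(self, config: CnnHeadConfig, d_model: int):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.d_model = d_model
        self.conv_w = [Tensor(rng.normal(0, np.sqrt(2.0 / (k * d_model + f)),
                                         size=(k * d_model, f)), requires_grad=True)
                       for k, f in zip(config.kernel_sizes, config.filter_counts)]
        self.conv_b = [Tensor(np.zeros(f), requires_grad=True)
                       for f in config.filter_counts]
        self.dense = nn.Dense(config.pooled_width, config.dense_width, rng)
        self.hw_t = nn.Dense(config.dense_width, config.dense_width, rng)
        self.hw_h = nn.Dense(config.dense_width, config.dense_width, rng)
        # bias the transform gate towards carry at init (highway convention)
        self.hw_t.b.data[:] = -1.0
        n_out = 1 if config.task == "regression" else 2
        self.out = nn.Dense(config.dense_width, n_out, rng)

    # -- padding -------------------------------------------------------
    def pad_input(self, x: np.ndarray) -> np.ndarray:
        """Right-pad (L, D) or (B, L, D) with zeros by one full max-kernel
        window (guarantees an all-zero window exists for every kernel)."""
        kmax = max(self.config.kernel_sizes)
        pad = [(0, 0)] * (x.ndim - 2) + [(0, kmax), (0, 0)]
        return np.pad(x, pad)

    # -- training forward (autodiff) -----------------------------------
    def __call__(self, x: Tensor, drop_rng: np.random.Generator | None = None) -> Tensor:
        pooled = []
        for k, w, b in zip(self.config.kernel_sizes, self.conv_w, self.conv_b):
            conv = (x.unfold1d(k) @ w + b).relu()
            pooled.append(conv.max(axis=1))
        z = nn.concatenate(pooled, axis=-1)
        if drop_rng is not None and self.config.dropout > 0:
            z = z * Tensor(nn.dropout_mask(z.shape, self.config.dropout, drop_rng))
        d = self.dense(z).relu()
        t = self.hw_t(d).sigmoid()
        h = self.hw_h(d).relu()
        y = t * h + (1.0 - t) * d
        return self.out(y)

    # -- plain forward with recorded intermediates (for LRP) -----------
    def forward_trace(self, x: np.ndarray) -> dict:
        """x: (L, D) single unpadded embedding; returns all activations."""
        xp = self.pad_input(x)
        L = xp.shape[0]
        trace = {"input": x, "padded": xp}
        pooled, argmaxes, conv_acts, windows = [], [], [], []
        for k, w, b in zip(self.config.kernel_sizes, self.conv_w, self.conv_b):
            W = L - k + 1
            u = np.lib.stride_tricks.sliding_window_view(xp, (k,), axis=0)
            u = np.ascontiguousarray(u.transpose(0, 2, 1)).reshape(W, k * self.d_model)
            act = np.maximum(u @ w.data + b.data, 0.0)       # (W, F)
            am = np.argmax(act, axis=0)                      # first max wins
            pooled.append(act[am, np.arange(act.shape[1])])
            argmaxes.append(am)
            conv_acts.append(act)
            windows.append(u)
        z = np.concatenate(pooled)
        d_pre = z @ self.dense.w.data + self.dense.b.data
        d = np.maximum(d_pre, 0.0)
        t = 1.0 / (1.0 + np.exp(-(d @ self.hw_t.w.data + self.hw_t.b.data)))
        h = np.maximum(d @ self.hw_h.w.data + self.hw_h.b.data, 0.0)
        y = t * h + (1.0 - t) * d
        out = y @ self.out.w.data + self.out.b.data
        trace.update(pooled=z, per_kernel_pooled=pooled, argmaxes=argmaxes,
                     conv_acts=conv_acts, windows=windows,
                     dense_out=d, gate=t, transformed=h, highway_out=y,
                     output=out)
        return trace


def build_head(config: CnnHeadConfig, d_model: int) -> CnnHead:
    return CnnHead(config, d_model)


@dataclass
class QsarModel:
    encoder: Canonicalizer
    head: CnnHead
    config: CnnHeadConfig
    training_log: list = field(default_factory=list)

    @property
    def task(self) -> str:
        return self.config.task


def encoder_hash(encoder: Canonicalizer) -> str:
    h = hashlib.sha256()
    for name in sorted(encoder.state_arrays()):
        h.update(name.encode())
        h.update(encoder.state_arrays()[name].tobytes())
    return h.hexdigest()[:16]


# -- data plumbing -----------------------------------------------------

def _embed_matrix(encoder: Canonicalizer, smiles_list: Sequence[str],
                  batch_size: int = 128) -> tuple[np.ndarray, np.ndarray]:
    """Stack embeddings into (B, Lmax, D) with per-item true lengths."""
    embs = []
    for lo in range(0, len(smiles_list), batch_size):
        embs.extend(batch_extract(encoder, smiles_list[lo:lo + batch_size]))
    lengths = np.array([e.matrix.shape[0] for e in embs])
    Lmax = int(lengths.max())
    D = embs[0].matrix.shape[1]
    out = np.zeros((len(embs), Lmax, D))
    for i, e in enumerate(embs):
        out[i, :e.matrix.shape[0]] = e.matrix
    return out, lengths


def _targets(records: Sequence[QsarRecord], task: str) -> np.ndarray:
    y = np.array([r.y for r in records], dtype=np.float64)
    if task == "classification":
        uniq = set(np.unique(y))
        if not uniq <= {0.0, 1.0}:
            raise ValueError("classification targets must be 0/1")
    return y


def _loss_tensor(head: CnnHead, out: Tensor, y: np.ndarray) -> Tensor:
    if head.config.task == "regression":
        diff = out.reshape(out.shape[0]) - Tensor(y)
        return (diff * diff).mean()
    logp = out.log_softmax(axis=-1)
    picked = logp.take_along_last(y.astype(np.int64))
    return -picked.mean()


def train_qsar(
    records: Sequence[QsarRecord],
    encoder: Canonicalizer,
    config: CnnHeadConfig,
    head: CnnHead | None = None,
) -> QsarModel:
    """Train the head on (already augmented) records; the encoder is frozen.

    The early-stopping holdout is drawn at parent-molecule level so that
    augmented copies of one molecule never straddle the split.
    """
    records = list(records)
    parents = sorted({r.parent_id or r.id or str(i) for i, r in enumerate(records)})
    if len(parents) < 20:
        raise ValueError(f"need >= 20 parent molecules, got {len(parents)}")
    y_all = _targets(records, config.task)
    if config.task == "regression" and float(np.var(y_all)) == 0.0:
        raise ValueError("target has zero variance")
    if config.task == "classification" and len(np.unique(y_all)) < 2:
        raise ValueError("classification needs both classes")

    rng = np.random.default_rng(config.seed)
    n_hold = max(1, int(round(config.holdout_fraction * len(parents))))
    hold_parents = set(rng.choice(parents, size=n_hold, replace=False).tolist())
    hold_idx = [i for i, r in enumerate(records)
                if (r.parent_id or r.id) in hold_parents]
    train_idx = [i for i in range(len(records)) if i not in set(hold_idx)]
    if not train_idx or not hold_idx:
        raise ValueError("degenerate holdout split")

    enc_hash_before = encoder_hash(encoder)
    X, _ = _embed_matrix(encoder, [r.smiles for r in records])
    head = head or build_head(config, encoder.config.d_model)
    X_pad = head.pad_input(X)
    Xtr, ytr = X_pad[train_idx], y_all[train_idx]
    Xho, yho = X_pad[hold_idx], y_all[hold_idx]

    params = head.parameters()
    opt = nn.Adam(params, lr=config.learning_rate)
    drop_rng = np.random.default_rng(config.seed + 1)
    best_loss, best_state, best_epoch = np.inf, None, -1
    log = []
    order = np.arange(len(train_idx))
    for epoch in range(config.max_epochs):
        rng.shuffle(order)
        tr_losses = []
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            out = head(Tensor(Xtr[idx]), drop_rng)
            loss = _loss_tensor(head, out, ytr[idx])
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(params, 5.0)
            opt.step()
            tr_losses.append(float(loss.data))
        hold_loss = float(_loss_tensor(head, head(Tensor(Xho)), yho).data)
        log.append({"epoch": epoch + 1, "train_loss": float(np.mean(tr_losses)),
                    "holdout_loss": hold_loss, "lr": config.learning_rate})
        if hold_loss < best_loss:
            best_loss, best_epoch = hold_loss, epoch
            best_state = {k: v.copy() for k, v in head.state_arrays().items()}
        elif epoch - best_epoch >= config.patience:
            logger.info("early stop at epoch %d (best %d)", epoch + 1, best_epoch + 1)
            break
    if best_state is not None:
        head.load_state_arrays(best_state)
    if encoder_hash(encoder) != enc_hash_before:
        raise RuntimeError("encoder weights changed during QSAR training")
    return QsarModel(encoder=encoder, head=head, config=config, training_log=log)


# -- inference ---------------------------------------------------------

def predict_batch(model: QsarModel, smiles_list: Sequence[str]) -> np.ndarray:
    X, _ = _embed_matrix(model.encoder, smiles_list)
    out = model.head(Tensor(model.head.pad_input(X))).data
    if model.config.task == "regression":
        return out[:, 0]
    z = out - out.max(axis=-1, keepdims=True)
    p = np.exp(z)
    return (p / p.sum(axis=-1, keepdims=True))[:, 1]


def predict_raw(model: QsarModel, smiles: str) -> float:
    return float(predict_batch(model, [smiles])[0])


# -- persistence -------------------------------------------------------

def save_qsar_model(model: QsarModel, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    save_checkpoint(model.encoder, path.with_name(path.stem + "_encoder"))
    np.savez(path.with_suffix(".npz"), **model.head.state_arrays())
    sidecar = {"head_config": asdict(model.config),
               "d_model": model.encoder.config.d_model,
               "training_log": model.training_log}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_qsar_model(path) -> QsarModel:
    path = Path(path)
    encoder = load_checkpoint(path.with_name(path.stem + "_encoder"))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = sidecar["head_config"]
    cfg["kernel_sizes"] = tuple(cfg["kernel_sizes"])
    cfg["filter_counts"] = tuple(cfg["filter_counts"])
    config = CnnHeadConfig(**cfg)
    head = CnnHead(config, sidecar["d_model"])
    with np.load(path.with_suffix(".npz")) as arrays:
        head.load_state_arrays(dict(arrays))
    return QsarModel(encoder=encoder, head=head, config=config,
                     training_log=sidecar.get("training_log", []))
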