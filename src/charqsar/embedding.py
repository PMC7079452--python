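"""Frozen-encoder dynamic embeddings: one row per token, context-dependent."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .canonicalizer import Canonicalizer, _pad_batch
from .tokenizer_io import TokenSequence, tokenize

__all__ = ["DynamicEmbedding", "extract_embedding", "batch_extract"]


@dataclass(frozen=True)
class DynamicEmbedding:
    matrix: np.ndarray            # (n_tokens, d_model)
    tokens: TokenSequence
    smiles: str

    def __post_init__(self):
        if self.matrix.shape[0] != len(self.tokens.ids):
            raise ValueError("embedding rows must align with tokens")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite embedding values")


def extract_embedding(model: Canonicalizer, smiles: str) -> DynamicEmbedding:
    """Encoder forward only (no dropout, weights untouched); rows cover all
    tokens including the start/end markers."""
    seq = tokenize(smiles, model.vocab)
    ids = np.asarray([seq.ids], dtype=np.int64)
    out = model.encode(ids).data[0]
    return DynamicEmbedding(matrix=out.copy(), tokens=seq, smiles=seq.text)


def batch_extract(model: Canonicalizer, smiles_list: Sequence[str]) -> list[DynamicEmbedding]:
    """Batched extraction; padding is masked so rows match single-item calls."""
    if not smiles_list:
        raise ValueError("empty batch")
    seqs = []
    for i, s in enumerate(smiles_list):
        try:
            seqs.append(tokenize(s, model.vocab))
        except Exception as exc:
            raise ValueError(f"item {i}: {exc}") from exc
    ids = _pad_batch([q.ids for q in seqs], model.vocab.pad_id)
    out = model.encode(ids).data
    return [
        DynamicEmbedding(matrix=out[i, :len(q.ids)].copy(), tokens=q, smiles=q.text)
        for i, q in enumerate(seqs)
    ]
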