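"""Augmented-consensus inference and evaluation statistics."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .augmentation import CanonOracle, enumerate_smiles
from .qsar_textcnn import QsarModel, predict_batch

__all__ = [
    "ConsensusPrediction", "predict_consensus",
    "r_squared", "auc", "bootstrap_sem",
]


@dataclass(frozen=True)
class ConsensusPrediction:
    mean: float
    std: float
    n_variants: int
    per_variant: tuple

    def __post_init__(self):
        if len(self.per_variant) != self.n_variants:
            raise ValueError("n_variants must match per_variant length")


def predict_consensus(model: QsarModel, smiles: str, n_augment: int = 10,
                      seed: int = 0, oracle: CanonOracle | None = None) -> ConsensusPrediction:
    """Average prediction over canonical + n random SMILES writings; the
    spread across writings doubles as a confidence estimate."""
    if n_augment > 0 and oracle is None:
        raise ValueError("augmented consensus requires an oracle")
    variants = [oracle.canonical(smiles) if oracle is not None else smiles]
    if n_augment > 0:
        variants += enumerate_smiles(smiles, n_augment, seed=seed, oracle=oracle)
    preds = predict_batch(model, variants)
    return ConsensusPrediction(
        mean=float(np.mean(preds)),
        std=float(np.std(preds)),
        n_variants=len(variants),
        per_variant=tuple(float(p) for p in preds),
    )


def _check_xy(y, y_hat):
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and y_hat must be equal-length 1-D arrays (n >= 2)")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(y_hat))):
        raise ValueError("non-finite values in metric inputs")
    return y, y_hat


def r_squared(y, y_hat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative)."""
    y, y_hat = _check_xy(y, y_hat)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("target variance is zero")
    ss_res = float(((y - y_hat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def auc(labels, scores) -> float:
    """Probability that a random positive outscores a random negative,
    ties counted one half (rank/Mann-Whitney formulation)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    # midrank computation via double argsort on the pooled scores
    pooled = np.concatenate([pos, neg])
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_scores = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    r_pos = ranks[:len(pos)].sum()
    n_p, n_n = len(pos), len(neg)
    return float((r_pos - n_p * (n_p + 1) / 2.0) / (n_p * n_n))


def bootstrap_sem(y, y_hat, metric: Callable, B: int = 1000, seed: int = 0) -> float:
    """Standard error of a metric over B paired resamples with replacement."""
    if B < 100:
        raise ValueError("B must be >= 100")
    y, y_hat = _check_xy(y, y_hat)
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = []
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(metric(y[idx], y_hat[idx]))
        except ValueError:
            continue  # degenerate resample (one class / zero variance)
    if not vals:
        raise ValueError("all bootstrap resamples were degenerate")
    return float(np.std(vals))
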