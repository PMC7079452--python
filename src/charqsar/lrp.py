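"""Layer-wise relevance propagation through the CNN head.

Propagation starts at the output neuron (regression value, or the
positive-class pre-normalization score for classification), walks back
through output dense -> highway (signal-take-all: gates are constants
and receive nothing) -> dense -> de-max-pool -> per-kernel convolutions,
and stops at the encoder output, which is position-wise. Linear layers
use the epsilon rule with a sign-matched stabilizer; every step logs a
ledger row (incoming relevance, outgoing relevance, delta, bias share)
so bias dissipation is auditable, and a warning is raised when less
than half of the output signal reaches the input positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .embedding import extract_embedding
from .qsar_textcnn import QsarModel

__all__ = [
    "RelevanceVector", "LayerLedgerRow", "CharAtomMap", "AtomAttribution",
    "lrp_dense", "lrp_conv", "lrp_maxpool", "lrp_highway",
    "propagate", "propagate_trace", "applicability_flag",
    "map_chars_to_atoms", "atom_attribution",
    "EPS",
]

EPS = 1e-9

_AROMATIC = set("bcnops")
_TWO_CHAR = ("Cl", "Br")
_ELEMENT_START = set("ABCDEFGHIKLMNOPRSTVXYZ")


def _stab(z: np.ndarray, eps: float) -> np.ndarray:
    s = np.where(z >= 0, 1.0, -1.0)
    return z + s * eps


# -- domain types ------------------------------------------------------

@dataclass(frozen=True)
class RelevanceVector:
    """Per-token-position relevance (markers included), aligned to the
    embedding rows of the propagated SMILES."""
    per_position: tuple
    smiles: str

    def __post_init__(self):
        if not all(np.isfinite(self.per_position)):
            raise ValueError("non-finite relevance")

    @property
    def total(self) -> float:
        return float(sum(self.per_position))


@dataclass(frozen=True)
class LayerLedgerRow:
    layer: str
    r_upper: float          # relevance entering the backward step, R(L+1)
    r_lower: float          # relevance after the step, R(L)
    delta: float
    bias_pct: float

    @classmethod
    def make(cls, layer: str, r_upper: float, r_lower: float) -> "LayerLedgerRow":
        delta = r_upper - r_lower
        if r_upper != 0.0:
            bias_pct = 100.0 * delta / r_upper
        else:
            bias_pct = 0.0 if delta == 0.0 else float("inf")
        return cls(layer=layer, r_upper=float(r_upper), r_lower=float(r_lower),
                   delta=float(delta), bias_pct=float(bias_pct))


@dataclass(frozen=True)
class CharAtomMap:
    spans: tuple            # per heavy atom: tuple of character indices
    elements: tuple         # per heavy atom: element/bracket text
    syntax_only: tuple      # char indices not owned by any atom (empty string edge case)


@dataclass(frozen=True)
class AtomAttribution:
    contributions: tuple    # per heavy atom (input SMILES atom order)
    prediction: float
    n_rooted: int
    mean_bias_pct: float
    elements: tuple = ()
    marker_relevance: float = 0.0
    flags: tuple = ()


# -- propagation rules -------------------------------------------------

def lrp_dense(r_out: np.ndarray, weights: np.ndarray, bias: np.ndarray,
              inputs: np.ndarray, eps: float = EPS) -> tuple[np.ndarray, float]:
    """Epsilon rule for a dense layer z = x @ W + b."""
    r_out = np.asarray(r_out, dtype=np.float64)
    z = inputs @ weights + bias
    s = r_out / _stab(z, eps)
    r_in = inputs * (weights @ s)
    return r_in, float(r_out.sum() - r_in.sum())


def lrp_conv(r_out: np.ndarray, kernel: np.ndarray, bias: np.ndarray,
             inputs: np.ndarray, eps: float = EPS) -> tuple[np.ndarray, float]:
    """Conv1d as tied dense over unfolded windows.

    kernel: (k, D, F); inputs: (L, D); r_out: (W, F) with W = L - k + 1.
    """
    k, D, F = kernel.shape
    L = inputs.shape[0]
    W = L - k + 1
    u = np.lib.stride_tricks.sliding_window_view(inputs, (k,), axis=0)
    u = np.ascontiguousarray(u.transpose(0, 2, 1)).reshape(W, k * D)
    w2 = kernel.reshape(k * D, F)
    z = u @ w2 + bias
    s = r_out / _stab(z, eps)
    r_u = u * (s @ w2.T)                         # (W, k*D)
    r_in = np.zeros_like(inputs)
    r_u4 = r_u.reshape(W, k, D)
    for j in range(k):
        r_in[j:j + W] += r_u4[:, j, :]
    return r_in, float(r_out.sum() - r_in.sum())


def lrp_maxpool(r_out: np.ndarray, inputs: np.ndarray) -> np.ndarray:
    """Winner-take-all: all relevance to the (first) argmax per filter."""
    am = np.argmax(inputs, axis=0)
    r_in = np.zeros_like(inputs)
    r_in[am, np.arange(inputs.shape[1])] = r_out
    return r_in


def lrp_highway(r_out: np.ndarray, gate: np.ndarray, transformed: np.ndarray,
                carry: np.ndarray, eps: float = EPS) -> tuple[np.ndarray, np.ndarray]:
    """Signal-take-all split for y = g*h + (1-g)*x; gates get nothing."""
    c_t = gate * transformed
    c_c = (1.0 - gate) * carry
    s = r_out / _stab(c_t + c_c, eps)
    return c_t * s, c_c * s


# -- full backward pass ------------------------------------------------

def propagate_trace(head, trace: dict, neuron: int,
                    eps: float = EPS) -> tuple[np.ndarray, list[LayerLedgerRow]]:
    """Backward pass over a recorded forward trace; returns the relevance
    matrix on the (padded) input and the layer ledger."""
    cfg = head.config
    out = trace["output"]
    r0 = float(out[neuron])

    ledger = [LayerLedgerRow.make("Result", r0, r0)]

    # output dense: relevance only on the propagated neuron
    r_out_vec = np.zeros_like(out)
    r_out_vec[neuron] = r0
    r_hw, _ = lrp_dense(r_out_vec, head.out.w.data, head.out.b.data,
                        trace["highway_out"], eps)
    ledger.append(LayerLedgerRow.make("HighWay Output", r0, float(r_hw.sum())))

    # highway: split, then pull the transform branch through its dense
    r_t, r_c = lrp_highway(r_hw, trace["gate"], trace["transformed"],
                           trace["dense_out"], eps)
    r_d_t, _ = lrp_dense(r_t, head.hw_h.w.data, head.hw_h.b.data,
                         trace["dense_out"], eps)
    r_d = r_d_t + r_c
    ledger.append(LayerLedgerRow.make("HighWay Input", float(r_hw.sum()),
                                      float(r_d.sum())))

    # dense back to the pooled vector, then invert the max-pool
    r_z, _ = lrp_dense(r_d, head.dense.w.data, head.dense.b.data,
                       trace["pooled"], eps)
    ledger.append(LayerLedgerRow.make("DeMaxPool", float(r_d.sum()),
                                      float(r_z.sum())))

    # per-kernel: de-pool then conv back to the padded input
    r_input = np.zeros_like(trace["padded"])
    offset = 0
    D = head.d_model
    for k, f, w, b, act in zip(cfg.kernel_sizes, cfg.filter_counts,
                               head.conv_w, head.conv_b, trace["conv_acts"]):
        r_slice = r_z[offset:offset + f]
        offset += f
        r_windows = lrp_maxpool(r_slice, act)
        r_in_k, _ = lrp_conv(r_windows, w.data.reshape(k, D, f), b.data,
                             trace["padded"], eps)
        r_input += r_in_k
        ledger.append(LayerLedgerRow.make(f"Conv{k}", float(r_slice.sum()),
                                          float(r_in_k.sum())))

    ledger.append(LayerLedgerRow.make("Total", r0, float(r_input.sum())))
    return r_input, ledger


def propagate(model: QsarModel, smiles: str,
              eps: float = EPS) -> tuple[RelevanceVector, list[LayerLedgerRow]]:
    head = model.head
    emb = extract_embedding(model.encoder, smiles)
    trace = head.forward_trace(emb.matrix)
    neuron = 0 if head.config.task == "regression" else 1
    r_input, ledger = propagate_trace(head, trace, neuron, eps)
    # padded rows carry zero input, hence exactly zero relevance
    T = emb.matrix.shape[0]
    per_position = r_input[:T].sum(axis=1)
    return RelevanceVector(per_position=tuple(per_position), smiles=emb.smiles), ledger


def applicability_flag(ledger: Sequence[LayerLedgerRow]) -> str:
    """'warning' when less than 50% of the output relevance reached the
    input positions; exactly 50% counts as ok."""
    total = next((row for row in ledger if row.layer == "Total"), None)
    if total is None:
        raise ValueError("ledger has no Total row")
    if total.r_upper == 0.0:
        return "ok" if total.r_lower == 0.0 else "warning"
    fraction = total.r_lower / total.r_upper
    return "ok" if fraction >= 0.5 else "warning"


# -- character -> atom mapping -----------------------------------------

def map_chars_to_atoms(smiles: str) -> CharAtomMap:
    """Partition character positions among heavy atoms.

    Bracket atoms own everything from '[' to ']'; two-letter elements own
    both characters; ring digits, bond symbols, branch parentheses and
    other syntax fold into the nearest preceding atom (leading syntax
    folds forward into the first atom).
    """
    spans: list[list[int]] = []
    elements: list[str] = []
    pending: list[int] = []       # syntax before the first atom
    i = 0
    n = len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            j = smiles.index("]", i)
            spans.append(list(range(i, j + 1)))
            elements.append(smiles[i:j + 1])
            i = j + 1
        elif smiles[i:i + 2] in _TWO_CHAR:
            spans.append([i, i + 1])
            elements.append(smiles[i:i + 2])
            i += 2
        elif ch in _ELEMENT_START or ch in _AROMATIC:
            spans.append([i])
            elements.append(ch)
            i += 1
        else:
            # syntax: ring digit, %, bond, parenthesis, dot, stereo mark
            if spans:
                spans[-1].append(i)
            else:
                pending.append(i)
            i += 1
    if pending and spans:
        spans[0] = sorted(pending + spans[0])
        pending = []
    return CharAtomMap(
        spans=tuple(tuple(sorted(s)) for s in spans),
        elements=tuple(elements),
        syntax_only=tuple(pending),
    )


# -- per-atom attribution ----------------------------------------------

def _rooted_with_order(oracle, smiles: str, atom_index: int):
    fn = getattr(oracle, "rooted_variant_with_order", None)
    if fn is not None:
        return fn(smiles, atom_index)
    return oracle.rooted_variant(smiles, atom_index), None


def atom_attribution(model: QsarModel, smiles: str, oracle) -> AtomAttribution:
    """One rooted SMILES per heavy atom; propagate each; per-atom score is
    the mean (over rooted writings) of the relevance summed over that
    atom's characters. The prediction is the mean of per-writing outputs."""
    from .qsar_textcnn import predict_batch

    n_atoms = oracle.heavy_atom_count(smiles)
    contrib_sum = np.zeros(n_atoms)
    contrib_cnt = np.zeros(n_atoms)
    rooted_all, biases, flags = [], [], []
    marker_rel = 0.0
    for root in range(n_atoms):
        rooted, order = _rooted_with_order(oracle, smiles, root)
        rooted_all.append(rooted)
        rel, ledger = propagate(model, rooted)
        total = next(r for r in ledger if r.layer == "Total")
        biases.append(total.bias_pct)
        flags.append(applicability_flag(ledger))
        cmap = map_chars_to_atoms(rooted)
        if len(cmap.spans) != n_atoms:
            raise ValueError(
                f"rooted SMILES {rooted!r}: parsed {len(cmap.spans)} atoms, "
                f"expected {n_atoms}")
        pp = np.asarray(rel.per_position)
        marker_rel += float(pp[0] + pp[-1])
        for k, span in enumerate(cmap.spans):
            # char index c sits at token position c + 1 (after '^')
            val = float(sum(pp[c + 1] for c in span))
            orig = order[k] if order is not None else (root if k == 0 else None)
            if orig is None:
                continue
            contrib_sum[orig] += val
            contrib_cnt[orig] += 1
    if np.any(contrib_cnt == 0):
        raise RuntimeError("some atoms received no relevance samples")
    preds = predict_batch(model, rooted_all)
    input_map = map_chars_to_atoms(smiles)
    elements = input_map.elements if len(input_map.elements) == n_atoms else ()
    return AtomAttribution(
        contributions=tuple(contrib_sum / contrib_cnt),
        prediction=float(np.mean(preds)),
        n_rooted=n_atoms,
        mean_bias_pct=float(np.mean(biases)),
        elements=elements,
        marker_relevance=marker_rel / n_atoms,
        flags=tuple(flags),
    )
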