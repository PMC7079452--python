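"""Reusable neural layers built on the Tensor autodiff core."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Dense", "LayerNorm", "Embedding", "dropout_mask"]


class Module:
    """Base class: collects Tensor parameters from attributes and sub-modules."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def state_arrays(self, prefix: str = "") -> dict:
        """Flat name -> ndarray mapping for checkpointing."""
        out = {}
        for k, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                out[prefix + k] = v.data
            elif isinstance(v, Module):
                out.update(v.state_arrays(prefix + k + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.state_arrays(f"{prefix}{k}.{i}."))
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out[f"{prefix}{k}.{i}"] = item.data
        return out

    def load_state_arrays(self, arrays: dict, prefix: str = ""):
        for k, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                v.data = np.asarray(arrays[prefix + k], dtype=np.float64)
            elif isinstance(v, Module):
                v.load_state_arrays(arrays, prefix + k + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        item.load_state_arrays(arrays, f"{prefix}{k}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        item.data = np.asarray(arrays[f"{prefix}{k}.{i}"], dtype=np.float64)


class Dense(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.w = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.w
        if self.b is not None:
            y = y + self.b
        return y


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-6):
        self.g = Tensor(np.ones(d), requires_grad=True)
        self.b = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.g + self.b


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.w = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d), size=(n, d)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.w.take_rows(ids)


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout multiplier; identity when rate == 0."""
    if rate <= 0:
        return np.ones(shape)
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(np.float64) / keep
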