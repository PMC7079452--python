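"""Seeded toy-molecule fixtures: library generation, a toolkit-free
canonicalization oracle over an acyclic SMILES grammar, and
planted-property QSAR datasets with known per-atom ground truth.

The grammar covers single-bonded acyclic molecules over a small element
palette (C/N/O/S/F/Cl/Br), which keeps every string valid both under the
internal parser and under RDKit, while remaining small enough for
desk-scale sequence models to learn the normalization task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tokenizer_io import PairRecord, QsarRecord

__all__ = [
    "ToyLibrarySpec", "PlantedProperty", "GrammarOracle",
    "generate_toy_library", "grammar_canonical_pairs", "make_planted_dataset",
    "parse_acyclic_smiles", "HALOGENS",
]

HALOGENS = frozenset({"F", "Cl", "Br"})

_MAX_BONDS = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1}
_TWO_CHAR = ("Cl", "Br")


def parse_acyclic_smiles(smiles: str) -> tuple[list[str], list[list[int]]]:
    """Parse the acyclic single-bond subset into (elements, adjacency).

    Atom indices follow order of appearance in the string.
    """
    elements: list[str] = []
    adj: list[list[int]] = []
    stack: list[int] = []
    current = -1
    i = 0
    while i < len(smiles):
        two = smiles[i:i + 2]
        if two in _TWO_CHAR:
            sym, step = two, 2
        elif smiles[i] in _MAX_BONDS:
            sym, step = smiles[i], 1
        elif smiles[i] == "(":
            if current < 0:
                raise ValueError(f"branch before any atom in {smiles!r}")
            stack.append(current)
            i += 1
            continue
        elif smiles[i] == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' in {smiles!r}")
            current = stack.pop()
            i += 1
            continue
        else:
            raise ValueError(f"character {smiles[i]!r} outside toy grammar in {smiles!r}")
        idx = len(elements)
        elements.append(sym)
        adj.append([])
        if current >= 0:
            adj[current].append(idx)
            adj[idx].append(current)
        current = idx
        i += step
    if stack:
        raise ValueError(f"unbalanced '(' in {smiles!r}")
    if not elements:
        raise ValueError("empty SMILES")
    return elements, adj


def _render_with_order(elements, adj, root: int, order=None) -> tuple[str, list[int]]:
    """Serialize the tree from ``root``; also return atom emission order.

    With order=None children are sorted by their rendered string, giving
    the deterministic rendering used by the normal form."""

    def rec(node: int, parent: int) -> tuple[str, list[int]]:
        subs = [rec(ch, node) for ch in adj[node] if ch != parent]
        if order is None:
            subs.sort(key=lambda t: t[0])
        else:
            order.shuffle(subs)
        text = elements[node]
        emitted = [node]
        for s, e in subs[:-1]:
            text += f"({s})"
            emitted.extend(e)
        if subs:
            text += subs[-1][0]
            emitted.extend(subs[-1][1])
        return text, emitted

    return rec(root, -1)


def _render(elements, adj, root: int, order=None) -> str:
    return _render_with_order(elements, adj, root, order)[0]


class GrammarOracle:
    """CanonOracle over the toy grammar; normal form is the
    lexicographically smallest rendering over all root choices."""

    def canonical(self, smiles: str) -> str:
        elements, adj = parse_acyclic_smiles(smiles)
        return min(_render(elements, adj, r) for r in range(len(elements)))

    def random_variant(self, smiles: str, seed: int) -> str:
        """Re-root at a random terminal atom and shuffle branch order.

        Restricting roots to leaves keeps the per-molecule variant space
        small enough for desk-scale sequence models while still exercising
        genuine atom renumbering."""
        elements, adj = parse_acyclic_smiles(smiles)
        rng = np.random.default_rng(seed)
        leaves = [r for r in range(len(elements)) if len(adj[r]) <= 1]
        root = int(leaves[rng.integers(len(leaves))])
        return _render(elements, adj, root, order=rng)

    def rooted_variant(self, smiles: str, atom_index: int) -> str:
        return self.rooted_variant_with_order(smiles, atom_index)[0]

    def rooted_variant_with_order(self, smiles: str, atom_index: int) -> tuple[str, list[int]]:
        elements, adj = parse_acyclic_smiles(smiles)
        if not 0 <= atom_index < len(elements):
            raise IndexError(f"atom index {atom_index} out of range")
        return _render_with_order(elements, adj, atom_index)

    def heavy_atom_count(self, smiles: str) -> int:
        return len(parse_acyclic_smiles(smiles)[0])


@dataclass(frozen=True)
class ToyLibrarySpec:
    n_molecules: int = 100
    max_heavy_atoms: int = 8
    min_heavy_atoms: int = 2
    palette: tuple = (("C", 0.50), ("N", 0.10), ("O", 0.14),
                      ("F", 0.09), ("Cl", 0.09), ("Br", 0.08))
    chain_bias: float = 0.0     # probability of extending the last atom (chain-like growth)
    size_weights: tuple = ()    # optional sampling weights for heavy-atom counts min..max
    seed: int = 0


def generate_toy_library(spec: ToyLibrarySpec) -> list[str]:
    """Random acyclic molecules as canonical toy-grammar SMILES, unique,
    deterministic under the spec seed."""
    rng = np.random.default_rng(spec.seed)
    oracle = GrammarOracle()
    symbols = [s for s, _ in spec.palette]
    probs = np.array([p for _, p in spec.palette], dtype=float)
    probs /= probs.sum()
    library: list[str] = []
    seen: set[str] = set()
    attempts = 0
    size_range = np.arange(spec.min_heavy_atoms, spec.max_heavy_atoms + 1)
    size_p = None
    if spec.size_weights:
        if len(spec.size_weights) != len(size_range):
            raise ValueError("size_weights must cover min..max heavy atoms")
        size_p = np.asarray(spec.size_weights, dtype=float)
        size_p = size_p / size_p.sum()
    while len(library) < spec.n_molecules and attempts < spec.n_molecules * 200:
        attempts += 1
        n_atoms = int(rng.choice(size_range, p=size_p))
        elements = ["C"]  # root must allow growth
        adj: list[list[int]] = [[]]
        ok = True
        for _ in range(n_atoms - 1):
            open_slots = [i for i, el in enumerate(elements)
                          if len(adj[i]) < _MAX_BONDS[el]]
            if not open_slots:
                ok = False
                break
            last = len(elements) - 1
            if last in open_slots and rng.random() < spec.chain_bias:
                parent = last
            else:
                parent = int(rng.choice(open_slots))
            sym = str(rng.choice(symbols, p=probs))
            idx = len(elements)
            elements.append(sym)
            adj.append([parent])
            adj[parent].append(idx)
        if not ok:
            continue
        canon = min(_render(elements, adj, r) for r in range(len(elements)))
        if canon not in seen:
            seen.add(canon)
            library.append(canon)
    if len(library) < spec.n_molecules:
        raise RuntimeError("could not generate requested library size; "
                           "raise max_heavy_atoms or loosen the palette")
    # re-canonicalize through the public oracle as a self-check
    assert all(oracle.canonical(s) == s for s in library[:5])
    return library


def grammar_canonical_pairs(library: Sequence[str], n_variants: int,
                            seed: int = 0) -> list[PairRecord]:
    """Desk-scale canonicalization corpus: per molecule, one identity line
    plus n_variants (random variant >> normal form) lines."""
    oracle = GrammarOracle()
    pairs: list[PairRecord] = []
    for mi, smiles in enumerate(library):
        canon = oracle.canonical(smiles)
        pairs.append(PairRecord(source=canon, target=canon))
        for vi in range(n_variants):
            v = oracle.random_variant(smiles, seed=seed * 7919 + mi * 131 + vi)
            pairs.append(PairRecord(source=v, target=canon))
    return pairs


@dataclass(frozen=True)
class PlantedProperty:
    """Ground-truth structure->property rule with per-atom contributions."""

    rule: str = "halogen_count"            # halogen_count | halogen_oxygen | contains_halogen
    betas: tuple = (2.0, 0.0)
    noise_sd: float = 0.1
    task: str = "regression"               # regression | classification

    def atom_effects(self, elements: Sequence[str]) -> np.ndarray:
        eff = np.zeros(len(elements))
        for i, el in enumerate(elements):
            if el in HALOGENS:
                eff[i] = self.betas[0]
            elif self.rule == "halogen_oxygen" and el == "O":
                eff[i] = self.betas[1]
        return eff

    def value(self, elements: Sequence[str]) -> float:
        if self.rule == "contains_halogen":
            return float(any(el in HALOGENS for el in elements))
        return float(self.atom_effects(elements).sum())


def make_planted_dataset(library: Sequence[str], planted: PlantedProperty,
                         seed: int = 0):
    """Returns (records, atom_truth) where atom_truth maps record id to the
    per-atom ground-truth effect vector (atom order of the input SMILES)."""
    rng = np.random.default_rng(seed)
    records: list[QsarRecord] = []
    atom_truth: dict[str, np.ndarray] = {}
    for mi, smiles in enumerate(library):
        elements, _ = parse_acyclic_smiles(smiles)
        y = planted.value(elements)
        if planted.task == "regression" and planted.noise_sd > 0:
            y += float(rng.normal(0.0, planted.noise_sd))
        rid = f"mol{mi}"
        records.append(QsarRecord(smiles=smiles, y=y, id=rid, parent_id=rid))
        atom_truth[rid] = planted.atom_effects(elements)
    return records, atom_truth
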