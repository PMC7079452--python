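"""SMILES enumeration, canonicalization-pair generation and QSAR augmentation.

All chemistry goes through a ``CanonOracle``: either the RDKit-backed
implementation below or the dependency-free grammar oracle from
``synthetic_fixtures``. Variants are sampled with replacement — the
augmentation multiplier is fixed, duplicates are not removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from .tokenizer_io import PairRecord, QsarRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CanonOracle", "RDKitOracle", "AugmentationPolicy",
    "enumerate_smiles", "make_canonicalization_pairs", "augment_qsar_dataset",
]


class CanonOracle(Protocol):
    """Chemistry-toolkit contract used by augmentation and attribution."""

    def canonical(self, smiles: str) -> str: ...

    def random_variant(self, smiles: str, seed: int) -> str: ...

    def rooted_variant(self, smiles: str, atom_index: int) -> str: ...

    def heavy_atom_count(self, smiles: str) -> int: ...


class RDKitOracle:
    """Canonicalization/enumeration backed by RDKit."""

    def _mol(self, smiles: str):
        from rdkit import Chem
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"RDKit could not parse SMILES {smiles!r}")
        return mol

    def canonical(self, smiles: str) -> str:
        from rdkit import Chem
        return Chem.MolToSmiles(self._mol(smiles))

    def random_variant(self, smiles: str, seed: int) -> str:
        from rdkit.Chem import rdmolfiles
        return rdmolfiles.MolToRandomSmilesVect(self._mol(smiles), 1, randomSeed=int(seed) % (2**31 - 1) or 1)[0]

    def rooted_variant(self, smiles: str, atom_index: int) -> str:
        return self.rooted_variant_with_order(smiles, atom_index)[0]

    def rooted_variant_with_order(self, smiles: str, atom_index: int) -> tuple[str, list[int]]:
        """Rooted SMILES plus, per output atom, its index in the input molecule."""
        import ast

        from rdkit import Chem
        mol = self._mol(smiles)
        if not 0 <= atom_index < mol.GetNumAtoms():
            raise IndexError(f"atom index {atom_index} out of range for {smiles!r}")
        rooted = Chem.MolToSmiles(mol, rootedAtAtom=int(atom_index), canonical=True)
        order = list(ast.literal_eval(mol.GetProp("_smilesAtomOutputOrder")))
        return rooted, order

    def heavy_atom_count(self, smiles: str) -> int:
        return self._mol(smiles).GetNumHeavyAtoms()


@dataclass(frozen=True)
class AugmentationPolicy:
    n_augment: int = 10
    include_identity: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_augment < 0:
            raise ValueError("n_augment must be >= 0")


def enumerate_smiles(smiles: str, n: int, seed: int, oracle: CanonOracle) -> list[str]:
    """n random SMILES writings of one molecule (duplicates allowed)."""
    return [oracle.random_variant(smiles, seed=seed * 100003 + i) for i in range(n)]


def make_canonicalization_pairs(
    molecules: Sequence[str],
    policy: AugmentationPolicy,
    oracle: CanonOracle,
) -> list[PairRecord]:
    """Per molecule: n_augment (variant >> canonical) lines, plus an
    identity (canonical >> canonical) line when the policy asks for it."""
    pairs: list[PairRecord] = []
    for mi, smiles in enumerate(molecules):
        try:
            canon = oracle.canonical(smiles)
        except ValueError as exc:
            raise ValueError(f"molecule {mi} ({smiles!r}): {exc}") from exc
        if policy.include_identity:
            pairs.append(PairRecord(source=canon, target=canon))
        for v in enumerate_smiles(smiles, policy.n_augment,
                                  seed=policy.seed * 1009 + mi, oracle=oracle):
            pairs.append(PairRecord(source=v, target=canon))
    return pairs


def augment_qsar_dataset(
    records: Iterable[QsarRecord],
    policy: AugmentationPolicy,
    oracle: CanonOracle,
) -> list[QsarRecord]:
    """Expand each record to canonical + n variants, tagging the parent id
    so consensus grouping and leakage-safe splits remain possible."""
    out: list[QsarRecord] = []
    n_dropped = 0
    for ri, rec in enumerate(records):
        try:
            canon = oracle.canonical(rec.smiles)
        except ValueError:
            n_dropped += 1
            continue
        parent = rec.parent_id or rec.id or f"rec{ri}"
        out.append(QsarRecord(smiles=canon, y=rec.y, id=f"{parent}/canonical",
                              parent_id=parent))
        for vi, v in enumerate(enumerate_smiles(rec.smiles, policy.n_augment,
                                                seed=policy.seed * 1009 + ri,
                                                oracle=oracle)):
            out.append(QsarRecord(smiles=v, y=rec.y, id=f"{parent}/aug{vi}",
                                  parent_id=parent))
    if n_dropped:
        logger.warning("augment_qsar_dataset: dropped %d unparseable records", n_dropped)
    return out
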