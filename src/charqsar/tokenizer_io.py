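"""Character vocabulary, SMILES tokenization, and file I/O.

The vocabulary is a fixed set of 65 printable characters covering
drug-like SMILES (elements, charges, stereo, ring closures) plus the
sequence markers '^' (start) and '$' (end). A dedicated padding id sits
outside the character range, giving 66 ids in total. Tokenization is
strictly per character: 'Br' is two tokens, bracket atoms are spelled
out character by character.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

# 65 characters; the en dash sometimes seen in typeset copies of this
# alphabet is normalized to ASCII '-' (see Vocabulary.normalize).
VOCAB_CHARS = "^#%()+-./0123456789=@ABCDEFGHIKLMNOPRSTVXYZ[\\]abcdefgilmnoprstuy$"
START = "^"
END = "$"

__all__ = [
    "Vocabulary", "TokenSequence", "PairRecord", "QsarRecord",
    "default_vocabulary", "tokenize", "detokenize",
    "read_pair_file", "write_pair_file", "read_qsar_csv",
    "UnknownCharacterError", "PairFileFormatError",
    "VOCAB_CHARS", "START", "END",
]


class UnknownCharacterError(ValueError):
    def __init__(self, char: str, position: int, smiles: str):
        self.char = char
        self.position = position
        super().__init__(
            f"unknown character {char!r} at position {position} in {smiles!r}"
        )


class PairFileFormatError(ValueError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    """Immutable symbol table with start/end markers and a padding id."""

    symbols: tuple = tuple(VOCAB_CHARS)
    start_marker: str = START
    end_marker: str = END

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("vocabulary symbols must be unique")
        for m in (self.start_marker, self.end_marker):
            if m not in self.symbols:
                raise ValueError(f"marker {m!r} missing from vocabulary")
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.symbols)})

    @property
    def index_of(self) -> dict:
        return self._index

    @property
    def pad_id(self) -> int:
        return len(self.symbols)

    @property
    def size(self) -> int:
        """Number of ids including padding."""
        return len(self.symbols) + 1

    @property
    def start_id(self) -> int:
        return self._index[self.start_marker]

    @property
    def end_id(self) -> int:
        return self._index[self.end_marker]

    @staticmethod
    def normalize(smiles: str) -> str:
        """Map typographic dashes to the ASCII minus used in SMILES."""
        return smiles.replace("–", "-").replace("−", "-")

    def __contains__(self, char: str) -> bool:
        return char in self._index

    def __len__(self) -> int:
        return self.size


_DEFAULT = Vocabulary()


def default_vocabulary() -> Vocabulary:
    return _DEFAULT


@dataclass(frozen=True)
class TokenSequence:
    ids: tuple
    text: str

    def __len__(self):
        return len(self.ids)


@dataclass(frozen=True)
class PairRecord:
    source: str
    target: str


@dataclass
class QsarRecord:
    smiles: str
    y: float
    id: Optional[str] = None
    parent_id: Optional[str] = field(default=None)


def tokenize(smiles: str, vocab: Vocabulary = _DEFAULT) -> TokenSequence:
    """Character-level encoding: [start] + one id per character + [end]."""
    smiles = vocab.normalize(smiles)
    index = vocab.index_of
    ids = [vocab.start_id]
    for pos, ch in enumerate(smiles):
        if ch not in index:
            raise UnknownCharacterError(ch, pos, smiles)
        ids.append(index[ch])
    ids.append(vocab.end_id)
    return TokenSequence(ids=tuple(ids), text=smiles)


def detokenize(seq: TokenSequence | Iterable[int], vocab: Vocabulary = _DEFAULT) -> str:
    ids = list(seq.ids) if isinstance(seq, TokenSequence) else list(seq)
    if len(ids) < 2 or ids[0] != vocab.start_id or ids[-1] != vocab.end_id:
        raise ValueError("token sequence must start with '^' and end with '$'")
    chars = []
    for i in ids[1:-1]:
        if not (0 <= i < len(vocab.symbols)):
            raise ValueError(f"token id {i} not in vocabulary")
        chars.append(vocab.symbols[i])
    return "".join(chars)


_DELIM = ">>"


def read_pair_file(path) -> list[PairRecord]:
    """Read 'src >> dst' lines; whitespace around the delimiter is ignored."""
    pairs = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n = line.count(_DELIM)
            if n != 1:
                raise PairFileFormatError(
                    f"line {lineno}: expected exactly one '>>' delimiter, found {n}"
                )
            src, dst = (part.strip() for part in line.split(_DELIM))
            if not src or not dst:
                raise PairFileFormatError(f"line {lineno}: empty side in pair")
            pairs.append(PairRecord(source=src, target=dst))
    return pairs


def write_pair_file(pairs: Iterable[PairRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(f"{p.source} >> {p.target}\n")


def read_qsar_csv(path, smiles_col: str = "smiles", y_col: str = "y",
                  vocab: Vocabulary = _DEFAULT) -> list[QsarRecord]:
    """Load a QSAR table, dropping rows with bad targets or bad SMILES."""
    records: list[QsarRecord] = []
    n_dropped = 0
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or smiles_col not in reader.fieldnames \
                or y_col not in reader.fieldnames:
            raise ValueError(
                f"columns {smiles_col!r}/{y_col!r} not found in {path}"
            )
        for i, row in enumerate(reader):
            smiles = (row[smiles_col] or "").strip()
            try:
                y = float(row[y_col])
                if y != y or y in (float("inf"), float("-inf")):
                    raise ValueError
                tokenize(smiles, vocab)
            except (ValueError, UnknownCharacterError, TypeError):
                n_dropped += 1
                continue
            rid = row.get("id") or f"row{i}"
            records.append(QsarRecord(smiles=smiles, y=y, id=rid, parent_id=rid))
    if n_dropped:
        logger.warning("read_qsar_csv: dropped %d unusable rows from %s", n_dropped, path)
    if not records:
        raise ValueError(f"no usable rows in {path}")
    return records
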