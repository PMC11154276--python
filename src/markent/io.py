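"""Reading and writing sequences, alphabets and transition matrices.

Sequences live on disk as whitespace- or comma-separated nonnegative
integers, one sequence per line, or as FASTA records whose residues are
mapped to an integer alphabet through an explicit :class:`AlphabetMap`
(strict: an unmappable residue is an error naming its position, never
silently dropped, since dropped symbols would change the entropy).
Transition matrices are headerless CSV, L rows of L probabilities.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numpy.typing import NDArray

from .exceptions import AlphabetError, InvalidParameterError
from .markov import TransitionModel

__all__ = [
    "AlphabetMap",
    "DNA_MAP",
    "read_sequence",
    "read_integer_sequences",
    "write_integer_sequences",
    "read_transition_csv",
    "write_transition_csv",
]


@dataclass(frozen=True)
class AlphabetMap:
    """Bijective map from source symbols (characters) to ``0 .. L-1``."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols) or not self.symbols:
            raise InvalidParameterError("alphabet symbols must be non-empty and distinct")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def encode(self, text: Iterable[str]) -> NDArray[np.int64]:
        index = {sym: i for i, sym in enumerate(self.symbols)}
        out = []
        for pos, ch in enumerate(text):
            try:
                out.append(index[ch])
            except KeyError:
                raise AlphabetError(
                    f"symbol {ch!r} at position {pos} is not in the alphabet {self.symbols}"
                ) from None
        return np.array(out, dtype=np.int64)

    def decode(self, s: Sequence[int]) -> str:
        return "".join(self.symbols[int(i)] for i in s)


DNA_MAP = AlphabetMap(("A", "C", "G", "T"))


def read_integer_sequences(path: str | Path) -> list[NDArray[np.int64]]:
    """All integer sequences in a text file, one per line."""
    out = []
    for line in Path(path).read_text().splitlines():
        tokens = [t for t in re.split(r"[\s,]+", line.strip()) if t]
        if tokens:
            out.append(np.array([int(t) for t in tokens], dtype=np.int64))
    if not out:
        raise InvalidParameterError(f"{path}: no sequences found")
    return out


def _read_fasta(path: str | Path, alphabet: AlphabetMap) -> NDArray[np.int64]:
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidParameterError(f"{path}: no FASTA records found")
    residues = "".join(str(rec.seq).upper() for rec in records)
    return alphabet.encode(residues)


def read_sequence(
    path: str | Path,
    fmt: str = "integers",
    alphabet: AlphabetMap | None = None,
) -> NDArray[np.int64]:
    """One integer sequence from a file.

    ``fmt="integers"`` concatenates all lines of whitespace/comma-separated
    integers; ``fmt="fasta"`` concatenates the residues of every record and
    maps them through ``alphabet`` (default: strict DNA A,C,G,T -> 0..3).
    """
    if fmt == "integers":
        return np.concatenate(read_integer_sequences(path))
    if fmt == "fasta":
        return _read_fasta(path, alphabet or DNA_MAP)
    raise InvalidParameterError(f"unknown sequence format {fmt!r}")


def write_integer_sequences(path: str | Path, sequences: Iterable[Sequence[int]]) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(" ".join(str(int(v)) for v in s) + "\n")


def read_transition_csv(path: str | Path) -> TransitionModel:
    """Row-stochastic matrix from headerless CSV (L rows x L columns)."""
    t = np.loadtxt(path, delimiter=",", ndmin=2)
    return TransitionModel(t)


def write_transition_csv(path: str | Path, model: TransitionModel) -> None:
    np.savetxt(path, model.transitions, delimiter=",", fmt="%.17g")
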