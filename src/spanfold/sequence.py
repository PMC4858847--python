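"""Validated RNA sequences.

Positions are 1-based throughout the package: residue ``i`` of an
:class:`RnaSequence` of length ``N`` satisfies ``1 <= i <= N``.  Many
dynamic-programming quantities are instead indexed by *gap* coordinates
``0..N`` (the gap ``i`` sits between residues ``i`` and ``i+1``); a gap pair
``(i, j)`` encloses residues ``i+1..j`` and, when it denotes an outermost
base pair, pairs residues ``(i+1, j)``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

ALPHABET = "ACGUN"
#: residue -> integer code used by the numeric kernels
CODES = {c: k for k, c in enumerate(ALPHABET)}


class SequenceError(ValueError):
    """Raised for sequences containing symbols outside {A,C,G,U,T,N}."""


def clean_residues(raw: str) -> str:
    """Uppercase, map T->U and validate against the {A,C,G,U,N} alphabet."""
    s = raw.upper().replace("T", "U")
    bad = set(s) - set(ALPHABET)
    if bad:
        raise SequenceError(f"invalid residue symbol(s): {sorted(bad)}")
    if not s:
        raise SequenceError("empty sequence")
    return s


@dataclass(frozen=True)
class RnaSequence:
    """An RNA sequence with 1-based residue access.

    ``T`` is silently read as ``U`` and lowercase input is uppercased.
    """

    name: str
    residues: str = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", clean_residues(self.residues))

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, i: int) -> str:
        """1-based residue access."""
        if not 1 <= i <= self.n:
            raise IndexError(f"position {i} outside 1..{self.n}")
        return self.residues[i - 1]

    def codes(self) -> np.ndarray:
        """Integer codes, padded so that ``codes()[i]`` is residue ``i``.

        Index 0 is a sentinel (``N``) and never pairs.
        """
        arr = np.empty(self.n + 1, dtype=np.int8)
        arr[0] = CODES["N"]
        arr[1:] = [CODES[c] for c in self.residues]
        return arr

    def digest(self) -> str:
        return hashlib.sha1(self.residues.encode()).hexdigest()[:12]

    def subsequence(self, start: int, end: int, name: str | None = None) -> "RnaSequence":
        """Residues ``start..end`` (1-based inclusive)."""
        if not 1 <= start <= end <= self.n:
            raise IndexError(f"range {start}..{end} outside 1..{self.n}")
        return RnaSequence(name or f"{self.name}:{start}-{end}", self.residues[start - 1 : end])
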