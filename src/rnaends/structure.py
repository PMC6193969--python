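"""Pseudoknot-free secondary structures as pair tables.

A structure is a partial pairing of sequence positions: each position is
unpaired or paired with exactly one partner, pairs are non-crossing
(nested), and every hairpin loop spans at least three unpaired
nucleotides.  Internally the pairing is a 0-based partner tuple
(-1 = unpaired); all public accessors and dot-bracket I/O are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .sequence import NucleotideSequence

MIN_HAIRPIN = 3

#: canonical Watson-Crick pairs plus the G-U wobble, as code pairs (A=0, C=1, G=2, U=3)
WC_PAIRS = frozenset({(0, 3), (3, 0), (2, 1), (1, 2)})
WOBBLE_PAIRS = frozenset({(2, 3), (3, 2)})


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested pairing of positions 1..L."""

    partners: tuple[int, ...]  # 0-based; -1 for unpaired

    def __post_init__(self) -> None:
        _validate_partners(self.partners)

    # -- constructors -------------------------------------------------
    @classmethod
    def empty(cls, length: int) -> "SecondaryStructure":
        return cls(partners=(-1,) * length)

    @classmethod
    def from_pairs(cls, pairs, length: int) -> "SecondaryStructure":
        """Build from 1-based (i, j) pairs."""
        partners = [-1] * length
        for i, j in pairs:
            if not (1 <= i <= length and 1 <= j <= length):
                raise ValueError(f"pair ({i},{j}) outside 1..{length}")
            if i == j:
                raise ValueError(f"position {i} cannot pair with itself")
            a, b = min(i, j) - 1, max(i, j) - 1
            if partners[a] != -1 or partners[b] != -1:
                raise ValueError(f"position in pair ({i},{j}) already paired")
            partners[a], partners[b] = b, a
        return cls(partners=tuple(partners))

    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        partners = [-1] * len(db)
        stack: list[int] = []
        for k, ch in enumerate(db):
            if ch == "(":
                stack.append(k)
            elif ch == ")":
                if not stack:
                    raise ValueError(f"unmatched ')' at position {k + 1}")
                a = stack.pop()
                partners[a], partners[k] = k, a
            elif ch != ".":
                raise ValueError(f"invalid dot-bracket character {ch!r}")
        if stack:
            raise ValueError(f"unmatched '(' at position {stack[-1] + 1}")
        return cls(partners=tuple(partners))

    # -- accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.partners)

    @cached_property
    def partner_array(self) -> np.ndarray:
        return np.asarray(self.partners, dtype=np.int32)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """1-based (i, j) pairs with i < j."""
        return [(i + 1, j + 1) for i, j in enumerate(self.partners)
                if j > i]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def to_dotbracket(self) -> str:
        out = []
        for i, j in enumerate(self.partners):
            out.append("." if j < 0 else "(" if j > i else ")")
        return "".join(out)

    def validate_for(self, seq: NucleotideSequence,
                     allow_wobble: bool = True) -> None:
        """Check pair eligibility against a sequence (A-U, G-C, G-U)."""
        if len(seq) != len(self):
            raise ValueError("structure and sequence lengths differ")
        codes = seq.codes
        allowed = WC_PAIRS | WOBBLE_PAIRS if allow_wobble else WC_PAIRS
        for i, j in self.pairs:
            duo = (int(codes[i - 1]), int(codes[j - 1]))
            if duo not in allowed:
                raise ValueError(
                    f"pair ({i},{j}) = {seq.residues[i-1]}-{seq.residues[j-1]} "
                    "is not an eligible base pair"
                )


def _validate_partners(partners: tuple[int, ...]) -> None:
    L = len(partners)
    for i, j in enumerate(partners):
        if j < 0:
            continue
        if not (0 <= j < L) or j == i:
            raise ValueError(f"invalid partner {j + 1} for position {i + 1}")
        if partners[j] != i:
            raise ValueError(
                f"pairing not symmetric at positions {i + 1},{j + 1}")
        if j > i and j - i - 1 < MIN_HAIRPIN:
            raise ValueError(
                f"pair ({i + 1},{j + 1}) closes a hairpin loop shorter than "
                f"{MIN_HAIRPIN} nucleotides"
            )
    # nestedness: matched-parenthesis scan
    stack: list[int] = []
    for i, j in enumerate(partners):
        if j > i:
            stack.append(j)
        elif 0 <= j < i:
            if not stack or stack[-1] != i:
                raise ValueError(
                    f"pairs cross at position {i + 1}: structure is "
                    "pseudoknotted"
                )
            stack.pop()
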