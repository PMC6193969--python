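"""Validated RNA sequences.

A :class:`NucleotideSequence` is the unit every pipeline in this package
operates on: an identifier plus an ordered string of residues over the
alphabet {A, C, G, U}.  DNA-style input (``T``, lowercase) is normalized on
construction.  Positions are 1-based in every public interface, matching
dot-bracket convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

ALPHABET = "ACGU"
_CODE = {c: i for i, c in enumerate(ALPHABET)}


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA sequence with an identifier.

    Parameters
    ----------
    id:
        Text label (FASTA header word).
    residues:
        Letters over {A, C, G, U}; ``T``/lowercase accepted and normalized.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        normalized = self.residues.upper().replace("T", "U")
        bad = set(normalized) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residue(s) "
                f"{sorted(bad)!r}; allowed letters are A, C, G, U (T is "
                "accepted and mapped to U)"
            )
        if len(normalized) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", normalized)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    @cached_property
    def codes(self) -> np.ndarray:
        """Residues encoded as uint8 (A=0, C=1, G=2, U=3)."""
        arr = np.frombuffer(self.residues.encode("ascii"), dtype=np.uint8)
        out = np.empty(arr.shape, dtype=np.uint8)
        for letter, code in _CODE.items():
            out[arr == ord(letter)] = code
        return out

    def nucleotide_frequencies(self) -> dict[str, float]:
        """Fraction of A, C, G and U in the sequence."""
        L = len(self)
        return {c: self.residues.count(c) / L for c in ALPHABET}

    def region_str(self, region: tuple[int, int]) -> str:
        """Substring for a 1-based closed interval ``(start, end)``."""
        start, end = check_region(region, len(self))
        return self.residues[start - 1 : end]

    def replace_region(self, region: tuple[int, int], segment: str,
                       id: str | None = None) -> "NucleotideSequence":
        """Return a copy with the 1-based closed ``region`` replaced."""
        start, end = check_region(region, len(self), allow_empty=len(segment) == 0)
        if len(segment) != end - start + 1:
            raise ValueError(
                f"replacement length {len(segment)} does not match region "
                f"[{start},{end}] length {end - start + 1}"
            )
        new = self.residues[: start - 1] + segment + self.residues[end:]
        return NucleotideSequence(id if id is not None else self.id, new)


def check_region(region: tuple[int, int], length: int,
                 allow_empty: bool = False) -> tuple[int, int]:
    """Validate a 1-based closed interval against a sequence length."""
    start, end = region
    if allow_empty and end == start - 1 and 1 <= start <= length + 1:
        return start, end
    if not (1 <= start <= end <= length):
        raise ValueError(
            f"region [{start},{end}] is not a valid 1-based closed interval "
            f"within a sequence of length {length}"
        )
    return start, end
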