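"""Sequence fixtures and transformations for end-to-end distance controls.

Mirrors the control computations used throughout the package: mononucleotide
composition-preserving shuffles of a region, random sequences at a fixed GC
content with fixed A:U and G:C splits, tandem-repeat replacements (CA
repeats have low base-pairing potential), and the GC-content scan of mean
end-to-end distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distance import FjcParameters, ensemble_end_to_end
from .energy import EnergyModel, stack_count_model
from .sequence import NucleotideSequence, check_region
from .thermo import DEFAULT_SAMPLE_SIZE


@dataclass(frozen=True)
class CompositionSpec:
    """Target mononucleotide composition.

    ``gc_fraction`` is P(G or C); among the G/C letters a fraction
    ``gc_ratio`` are G, and among the A/U letters a fraction ``au_ratio``
    are A.
    """

    gc_fraction: float = 0.5
    au_ratio: float = 0.5
    gc_ratio: float = 0.5

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "au_ratio", "gc_ratio"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def probabilities(self) -> np.ndarray:
        """P(A), P(C), P(G), P(U)."""
        gc, au, gr = self.gc_fraction, self.au_ratio, self.gc_ratio
        return np.array([(1 - gc) * au, gc * (1 - gr), gc * gr,
                         (1 - gc) * (1 - au)])


def shuffle_region(seq: NucleotideSequence, region: tuple[int, int],
                   seed: int = 0) -> NucleotideSequence:
    """Permute the letters of a 1-based closed region uniformly at random.

    Composition conservation is exact (the region letters are an anagram
    of the original); everything outside the region is untouched.
    """
    start, end = check_region(region, len(seq))
    rng = np.random.default_rng(seed)
    letters = list(seq.region_str((start, end)))
    rng.shuffle(letters)
    return seq.replace_region((start, end), "".join(letters))


def random_sequence(length: int, spec: CompositionSpec = CompositionSpec(),
                    seed: int = 0, id: str | None = None) -> NucleotideSequence:
    """Draw letters i.i.d. from the composition spec."""
    if length < 1:
        raise ValueError("length must be at least 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=length, p=spec.probabilities)
    residues = "".join("ACGU"[int(c)] for c in draws)
    return NucleotideSequence(id if id is not None else f"random_{seed}",
                              residues)


def repeat_construct(unit: str, copies: int, insert_into: NucleotideSequence,
                     region: tuple[int, int]) -> NucleotideSequence:
    """Replace a region with ``copies`` tandem copies of ``unit``.

    The repeat length must match the region length exactly (e.g. 53 CA
    repeats replacing 106 nucleotides).
    """
    if copies < 0:
        raise ValueError("copies must be non-negative")
    segment = unit * copies
    start, end = check_region(region, len(insert_into),
                              allow_empty=len(segment) == 0)
    span = end - start + 1
    if len(segment) != span:
        raise ValueError(
            f"repeat of length {len(segment)} ({copies} x {unit!r}) does "
            f"not match region [{start},{end}] length {span}"
        )
    if not segment:
        return insert_into
    return insert_into.replace_region((start, end), segment)


def gc_scan(length: int = 1327, spec: CompositionSpec = CompositionSpec(),
            step_percent: int = 5, n_per_point: int = 100,
            model: EnergyModel | None = None,
            fjc: FjcParameters = FjcParameters(), seed: int = 0,
            samples_per_sequence: int = DEFAULT_SAMPLE_SIZE) -> pd.DataFrame:
    """Mean end-to-end distance as a function of GC content.

    For each GC value from 0 to 100% in ``step_percent`` increments,
    generates ``n_per_point`` random sequences (A:U and G:C splits taken
    from ``spec``), runs the ensemble end-to-end pipeline on each, and
    averages the per-sequence means.  Returns a DataFrame with columns
    ``gc_percent``, ``mean_distance_nm``, ``sd_nm``.
    """
    if step_percent < 1 or 100 % step_percent != 0:
        raise ValueError("step_percent must divide 100")
    if n_per_point < 1:
        raise ValueError("n_per_point must be at least 1")
    model = model if model is not None else stack_count_model()
    rng = np.random.default_rng(seed)
    rows = []
    for gc in range(0, 101, step_percent):
        point_spec = CompositionSpec(gc_fraction=gc / 100.0,
                                     au_ratio=spec.au_ratio,
                                     gc_ratio=spec.gc_ratio)
        means = np.empty(n_per_point)
        for k in range(n_per_point):
            s = random_sequence(length, point_spec,
                                seed=int(rng.integers(2**31 - 1)),
                                id=f"gc{gc}_{k}")
            dist = ensemble_end_to_end(s, model,
                                       count=samples_per_sequence,
                                       seed=int(rng.integers(2**31 - 1)),
                                       params=fjc)
            means[k] = dist.mean
        rows.append({"gc_percent": gc,
                     "mean_distance_nm": float(means.mean()),
                     "sd_nm": float(means.std(ddof=0))})
    return pd.DataFrame(rows)
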