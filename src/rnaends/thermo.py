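"""Equilibrium ensembles of nested secondary structures.

Three routes into the same Boltzmann ensemble:

* :func:`enumerate_structures` — exhaustive recursion over every admissible
  structure (small sequences only); the oracle the dynamic programming is
  tested against.
* :func:`partition_function` — inside/outside dynamic programming giving
  the partition value Z and the full base-pair probability matrix
  P(i, j) = (sum of Boltzmann weights of structures containing (i, j)) / Z.
* :func:`sample_structures` — stochastic traceback drawing structures with
  probability equal to their Boltzmann probability (conditional-probability
  traceback over the inside arrays), seeded and reproducible.

The mean base-pairing probability — the average over nucleotide positions
of the probability of being paired — is the primary fitness used by the
sequence-design genetic algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import _kernels
from .energy import EnergyModel
from .sequence import NucleotideSequence
from .structure import SecondaryStructure

ENUMERATION_GUARD = 30
DEFAULT_SAMPLE_SIZE = 1000

#: scaled partition value is renormalized into this magnitude window so that
#: inside x outside products stay within float64 range
_LOG_WINDOW = 120.0 * math.log(10.0)


@dataclass(frozen=True)
class PairProbabilityMatrix:
    """Boltzmann pair probabilities and the partition value.

    ``P`` is symmetric with ``P[i-1, j-1]`` the probability that positions
    i and j (1-based) pair; ``log_z`` is the natural log of the partition
    value (``Z`` itself overflows float64 beyond a few hundred
    nucleotides).
    """

    log_z: float
    P: np.ndarray
    expected_pairs: float

    @property
    def Z(self) -> float:
        return math.exp(self.log_z) if self.log_z < 700 else math.inf

    @property
    def length(self) -> int:
        return self.P.shape[0]

    def probability(self, i: int, j: int) -> float:
        """P(i, j) for 1-based positions."""
        return float(self.P[i - 1, j - 1])

    def probability_paired(self, i: int) -> float:
        """Probability that 1-based position i is paired with anything."""
        return float(self.P[i - 1].sum())


@dataclass(frozen=True)
class EnsembleSample:
    """An ordered, seeded Boltzmann sample of structures."""

    structures: list[SecondaryStructure]
    sample_size: int
    seed: int

    def __post_init__(self) -> None:
        if self.sample_size != len(self.structures):
            raise ValueError("sample_size does not match structure count")


class Partition:
    """Inside arrays for one (sequence, model) pair, reused across queries.

    Computes the scaled inside recursion once (with an adaptive rescaling
    loop keeping the scaled Z near magnitude one) and serves the partition
    value, pair probabilities, expected pair count and stochastic samples
    from it.
    """

    def __init__(self, seq: NucleotideSequence, model: EnergyModel):
        self.seq = seq
        self.model = model
        codes = seq.codes
        self.can, self.bst, self.biso = model.pair_tables(codes)
        L = len(seq)
        s = 1.0
        if L > 140:
            # rough per-position magnitude guess; the retry loop refines it
            bmax = max(float(self.bst.max()), 1.0) if L else 1.0
            s = (2.6 * bmax) ** 0.5
        # blind correction step small enough that log(zhat) cannot jump
        # across the entire float64 range in one move
        step = math.exp(min(0.7, 600.0 / max(L, 1)))
        for _ in range(200):
            W, Wd, Vx, Vxd, Vp, Vpd = _kernels.inside_dp(
                self.can, self.bst, self.biso, s)
            zhat = W[0, L]
            if math.isnan(zhat) or math.isinf(zhat):
                s *= step  # overflow somewhere: scale harder
                continue
            if zhat <= 0.0:
                s /= step  # underflow: scale less
                continue
            if abs(math.log(zhat)) > _LOG_WINDOW:
                # finite but out of window: renormalize exactly
                s *= math.exp(math.log(zhat) / L)
                continue
            if not (np.isfinite(W).all() and np.isfinite(Vx).all()):
                s *= step
                continue
            break
        else:  # pragma: no cover - would need a pathological model
            raise FloatingPointError("partition function failed to scale")
        self.s = s
        self.W, self.Wd, self.Vx, self.Vxd, self.Vp, self.Vpd = (
            W, Wd, Vx, Vxd, Vp, Vpd)
        self.log_z = math.log(zhat) + L * math.log(s)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def expected_pairs(self) -> float:
        """Exact Boltzmann-expected number of base pairs."""
        return float(self.Wd[0, self.length] / self.W[0, self.length])

    @property
    def mean_bp_probability(self) -> float:
        """Mean over positions of the probability of being paired."""
        return 2.0 * self.expected_pairs / self.length

    def pair_probabilities(self) -> PairProbabilityMatrix:
        P = _kernels.outside_dp(self.can, self.bst, self.biso, self.s,
                                self.W, self.Vx, self.Vp)
        return PairProbabilityMatrix(log_z=self.log_z, P=P,
                                     expected_pairs=self.expected_pairs)

    def sample_tables(self, count: int, seed: int) -> np.ndarray:
        """Raw partner tables, shape (count, L), int32, -1 = unpaired."""
        if count < 1:
            raise ValueError("sample count must be a positive integer")
        kernel_seed = int(seed) % (2**31 - 1)
        return _kernels.sample_dp(self.can, self.bst, self.biso, self.s,
                                  self.W, self.Vx, self.Vp, count,
                                  kernel_seed)

    def sample(self, count: int = DEFAULT_SAMPLE_SIZE,
               seed: int = 0) -> EnsembleSample:
        tables = self.sample_tables(count, seed)
        structures = [SecondaryStructure(partners=tuple(int(p) for p in row))
                      for row in tables]
        return EnsembleSample(structures=structures, sample_size=count,
                              seed=seed)


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def partition_function(seq: NucleotideSequence,
                       model: EnergyModel) -> PairProbabilityMatrix:
    """Partition value Z and base-pair probabilities P(i, j)."""
    return Partition(seq, model).pair_probabilities()


def mean_bp_probability(matrix: PairProbabilityMatrix) -> float:
    """Mean over positions of the probability of being paired.

    Equals (1/L) * sum_i P(position i paired) — each pair contributes to
    both of its positions.
    """
    return float(matrix.P.sum()) / matrix.length


def mean_pairing_probability(seq: NucleotideSequence,
                             model: EnergyModel) -> float:
    """Mean base-pairing probability straight from the inside recursion.

    Uses the pair-count derivative of the partition value (exact, and
    cheaper than materializing the full probability matrix); identical to
    ``mean_bp_probability(partition_function(seq, model))``.
    """
    return Partition(seq, model).mean_bp_probability


def sample_structures(seq: NucleotideSequence, model: EnergyModel,
                      count: int = DEFAULT_SAMPLE_SIZE,
                      seed: int = 0) -> EnsembleSample:
    """Draw ``count`` independent structures with Boltzmann probabilities."""
    return Partition(seq, model).sample(count=count, seed=seed)


def enumerate_structures(
        seq: NucleotideSequence,
        model: EnergyModel) -> list[tuple[SecondaryStructure, float]]:
    """Every admissible structure with its energy (exhaustive recursion).

    Intended as a brute-force oracle: structure counts grow exponentially,
    so sequences longer than the guard are refused outright.
    """
    L = len(seq)
    if L > ENUMERATION_GUARD:
        raise ValueError(
            f"sequence length {L} exceeds the enumeration guard "
            f"(L <= {ENUMERATION_GUARD}); use partition_function / "
            "sample_structures for longer sequences"
        )
    can, _, _ = model.pair_tables(seq.codes)

    @lru_cache(maxsize=None)
    def seg(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        # all pairings of inclusive segment i..j, as 0-based pair tuples
        if j - i < 4:
            return ((),)
        result = list(seg(i, j - 1))  # j unpaired
        for k in range(i, j - 3):
            if can[k, j]:
                for left in seg(i, k - 1) if k > i else ((),):
                    for inner in seg(k + 1, j - 1):
                        result.append(left + ((k, j),) + inner)
        return tuple(result)

    out = []
    for pairs in seg(0, L - 1):
        structure = SecondaryStructure.from_pairs(
            [(i + 1, j + 1) for i, j in pairs], L)
        out.append((structure, model.structure_energy(seq, structure)))
    return out
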