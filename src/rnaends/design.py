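"""Genetic-algorithm design of intrinsically unstructured RNA sequences.

A population of sequences is evolved — by per-nucleotide random mutation
and single-point crossover — to minimize the mean base-pairing probability
of the Boltzmann ensemble, the quantity that controls how far apart the
5' and 3' ends sit.  Truncation selection with elitism makes the best
fitness non-increasing across iterations.

Two fitness modes:

``min_bp``
    fitness = mean base-pairing probability.  Selection drives guanosines
    out of the sequence (G pairs with both C and, as a wobble, with U) and
    collapses linguistic complexity: the winners are low-complexity
    repeats of A, C and U.
``min_bp_with_complexity``
    fitness = mean bp probability + penalty_weight * max(0,
    complexity_floor - LC).  The linguistic-complexity floor keeps the
    evolved sequence non-repetitive while still unstructured.

Linguistic complexity LC is the product over word sizes k = 1..k_max of
U_k = (distinct k-mers observed) / min(4^k, L - k + 1); it lies in (0, 1],
equals 1 for maximally diverse sequences and collapses toward 0 for
homopolymers and short tandem repeats.

Only positions inside the configured region are mutable, but fitness is
always evaluated on the full sequence — base pairing is global.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .distance import FjcParameters, distances_from_tables
from .energy import EnergyModel, stack_count_model
from .sequence import ALPHABET, NucleotideSequence, check_region
from .thermo import DEFAULT_SAMPLE_SIZE, Partition


@dataclass(frozen=True)
class ComplexityScore:
    """Linguistic complexity: product of k-mer vocabulary usage fractions."""

    value: float
    k_max: int

    def __post_init__(self) -> None:
        if not (0.0 < self.value <= 1.0):
            raise ValueError("linguistic complexity must be in (0, 1]")

    def __float__(self) -> float:
        return self.value


def linguistic_complexity(seq: NucleotideSequence | str,
                          k_max: int = 6) -> ComplexityScore:
    """LC = prod_{k=1..k_max} (distinct k-mers) / min(4^k, L - k + 1)."""
    s = seq.residues if isinstance(seq, NucleotideSequence) else str(seq)
    L = len(s)
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    if k_max > L:
        raise ValueError(f"k_max {k_max} exceeds sequence length {L}")
    value = 1.0
    for k in range(1, k_max + 1):
        observed = len({s[i:i + k] for i in range(L - k + 1)})
        possible = min(4**k, L - k + 1)
        value *= observed / possible
    return ComplexityScore(value=value, k_max=k_max)


def mutate(seq: NucleotideSequence, region: tuple[int, int],
           mutation_rate: float, rng: np.random.Generator) -> NucleotideSequence:
    """Independently substitute each region position with rate ``mutation_rate``.

    A substituted position receives one of the three *other* nucleotides,
    uniformly; positions outside the 1-based closed region are untouched.
    """
    start, end = check_region(region, len(seq))
    if not (0.0 <= mutation_rate < 1.0):
        raise ValueError("mutation_rate must be in [0, 1)")
    residues = list(seq.residues)
    span = end - start + 1
    hits = np.flatnonzero(rng.random(span) < mutation_rate)
    for h in hits:
        pos = start - 1 + int(h)
        current = residues[pos]
        options = [c for c in ALPHABET if c != current]
        residues[pos] = options[int(rng.integers(3))]
    return NucleotideSequence(seq.id, "".join(residues))


def crossover(parent1: NucleotideSequence, parent2: NucleotideSequence,
              region: tuple[int, int],
              rng: np.random.Generator) -> NucleotideSequence:
    """Single-point crossover at a uniformly chosen cut inside the region.

    The child takes parent1 up to and including the cut position and
    parent2 after it.  Parents must have equal length and be identical
    outside the region.
    """
    if len(parent1) != len(parent2):
        raise ValueError("crossover parents must have equal lengths")
    start, end = check_region(region, len(parent1))
    outside = (parent1.residues[: start - 1] + parent1.residues[end:],
               parent2.residues[: start - 1] + parent2.residues[end:])
    if outside[0] != outside[1]:
        raise ValueError("crossover parents differ outside the region")
    cut = int(rng.integers(start, end + 1))  # 1-based, in [start, end]
    child = parent1.residues[:cut] + parent2.residues[cut:]
    return NucleotideSequence(parent1.id, child)


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm hyperparameters.

    ``region`` is the 1-based closed interval of mutable positions (None =
    whole sequence).  ``trajectory_sample_size`` structures are drawn per
    iteration for the end-to-end distance record; the final iteration uses
    ``final_sample_size``.
    """

    population_size: int = 50
    mutation_rate: float = 0.01
    crossover_rate: float = 0.3
    elite_count: int = 5
    iterations: int = 1000
    fitness_mode: str = "min_bp"
    complexity_floor: float = 0.35
    penalty_weight: float = 1.0
    k_max: int = 6
    region: tuple[int, int] | None = None
    seed: int = 0
    trajectory_sample_size: int = 100
    final_sample_size: int = DEFAULT_SAMPLE_SIZE


@dataclass(frozen=True)
class GaRecord:
    """State of the best individual at one iteration."""

    iteration: int
    sequence: str
    fitness: float
    mean_bp: float
    distance_nm: float
    complexity: float
    freq_a: float
    freq_c: float
    freq_g: float
    freq_u: float


@dataclass
class EvolutionTrajectory:
    """Per-iteration records of a design run (iteration 0 = input)."""

    records: list[GaRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def best_sequence(self) -> str:
        return self.records[-1].sequence

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def _validate_config(config: GaConfig, length: int) -> tuple[int, int]:
    if config.population_size < 2:
        raise ValueError("population_size must be at least 2")
    if not (0.0 < config.mutation_rate < 1.0):
        raise ValueError("mutation_rate must be in (0, 1)")
    if not (0.0 <= config.crossover_rate <= 1.0):
        raise ValueError("crossover_rate must be in [0, 1]")
    if not (1 <= config.elite_count <= config.population_size):
        raise ValueError("elite_count must be in [1, population_size]")
    if config.iterations < 0:
        raise ValueError("iterations must be non-negative")
    if config.fitness_mode not in ("min_bp", "min_bp_with_complexity"):
        raise ValueError(f"unknown fitness_mode {config.fitness_mode!r}")
    region = config.region if config.region is not None else (1, length)
    return check_region(region, length)


def evolve_sequence(seq: NucleotideSequence, config: GaConfig = GaConfig(),
                    model: EnergyModel | None = None,
                    fjc: FjcParameters = FjcParameters()) -> EvolutionTrajectory:
    """Evolve ``seq`` (whole or a region) toward an unstructured ensemble.

    Returns a trajectory with ``iterations + 1`` records; composition and
    complexity are reported for the mutable region, fitness for the full
    sequence.
    """
    region = _validate_config(config, len(seq))
    model = model if model is not None else stack_count_model()
    rng = np.random.default_rng(config.seed)
    cache: dict[str, tuple[float, Partition]] = {}

    def evaluate(individual: NucleotideSequence) -> tuple[float, Partition]:
        key = individual.residues
        hit = cache.get(key)
        if hit is not None:
            return hit
        part = Partition(individual, model)
        fitness = part.mean_bp_probability
        if config.fitness_mode == "min_bp_with_complexity":
            lc = linguistic_complexity(individual.region_str(region),
                                       config.k_max).value
            fitness += config.penalty_weight * max(
                0.0, config.complexity_floor - lc)
        cache[key] = (fitness, part)
        return fitness, part

    def record(it: int, best: NucleotideSequence, fitness: float,
               part: Partition, sample_size: int) -> GaRecord:
        tables = part.sample_tables(sample_size,
                                    int(rng.integers(2**31 - 1)))
        dist = float(distances_from_tables(tables, fjc).mean())
        segment = best.region_str(region)
        lc = linguistic_complexity(segment, min(config.k_max,
                                                len(segment))).value
        span = len(segment)
        return GaRecord(
            iteration=it, sequence=best.residues, fitness=fitness,
            mean_bp=part.mean_bp_probability, distance_nm=dist,
            complexity=lc,
            freq_a=segment.count("A") / span,
            freq_c=segment.count("C") / span,
            freq_g=segment.count("G") / span,
            freq_u=segment.count("U") / span,
        )

    population = [seq] + [
        mutate(seq, region, config.mutation_rate, rng)
        for _ in range(config.population_size - 1)
    ]
    scored = sorted(((evaluate(ind)[0], k, ind)
                     for k, ind in enumerate(population)),
                    key=lambda t: (t[0], t[1]))

    trajectory = EvolutionTrajectory()
    best_fit, _, best_ind = scored[0]
    trajectory.records.append(
        record(0, best_ind, best_fit, cache[best_ind.residues][1],
               config.trajectory_sample_size
               if config.iterations else config.final_sample_size))

    n_parents = max(2, config.population_size // 2)
    for it in range(1, config.iterations + 1):
        parents = [ind for _, _, ind in scored[:n_parents]]
        children = [ind for _, _, ind in scored[:config.elite_count]]
        while len(children) < config.population_size:
            if config.crossover_rate > 0 and rng.random() < config.crossover_rate:
                i, j = rng.choice(len(parents), size=2, replace=False)
                child = crossover(parents[int(i)], parents[int(j)],
                                  region, rng)
            else:
                child = parents[int(rng.integers(len(parents)))]
            children.append(mutate(child, region, config.mutation_rate, rng))
        population = children
        scored = sorted(((evaluate(ind)[0], k, ind)
                         for k, ind in enumerate(population)),
                        key=lambda t: (t[0], t[1]))
        best_fit, _, best_ind = scored[0]
        sample_size = (config.final_sample_size if it == config.iterations
                       else config.trajectory_sample_size)
        trajectory.records.append(
            record(it, best_ind, best_fit, cache[best_ind.residues][1],
                   sample_size))
        # drop stale cache entries to bound memory on long runs
        if len(cache) > 4 * config.population_size:
            keep = {ind.residues for ind in population}
            for key in [k for k in cache if k not in keep]:
                del cache[key]
    return trajectory
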