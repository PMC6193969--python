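"""Shared fixtures and independent oracle helpers.

The oracle helpers recompute ensemble quantities by brute force from the
exhaustive structure enumeration, with their own exterior-loop counter, so
the dynamic programming, the sampler and the distance pipeline are checked
against arithmetic that shares no code path with them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from rnaends import (NucleotideSequence, enumerate_structures,
                     stack_count_model, uniform_model)


@pytest.fixture(scope="session")
def uniform():
    return uniform_model()


@pytest.fixture(scope="session")
def stacking():
    return stack_count_model()


def make_random_sequences(n, min_len, max_len, seed):
    """Uniformly random ACGU sequences for oracle comparisons."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        out.append(NucleotideSequence(
            f"rand{k}", "".join("ACGU"[c] for c in rng.integers(0, 4, L))))
    return out


def exterior_counts_reference(structure):
    """Independent exterior-loop counter: n unpaired, m helices, top level."""
    partners = structure.partners
    depth = 0
    n = 0
    m = 0
    for i, j in enumerate(partners):
        if j > i:
            if depth == 0:
                m += 1
            depth += 1
        elif 0 <= j < i:
            depth -= 1
        elif depth == 0:
            n += 1
    return n, m


def boltzmann_summary(seq, model, fjc=None):
    """Exact ensemble quantities from exhaustive enumeration.

    Returns (Z, P matrix, mean bp probability, weighted mean FJC distance,
    list of (structure, weight)).
    """
    L = len(seq)
    rt = model.rt
    items = enumerate_structures(seq, model)
    weights = [math.exp(-e / rt) for _, e in items]
    Z = sum(weights)
    P = np.zeros((L, L))
    mean_bp = 0.0
    mean_dist = 0.0
    for (structure, _), w in zip(items, weights):
        for i, j in structure.pairs:
            P[i - 1, j - 1] += w
            P[j - 1, i - 1] += w
        mean_bp += w * 2 * structure.n_pairs / L
        if fjc is not None:
            n, m = exterior_counts_reference(structure)
            d = math.sqrt(fjc.a**2 * n**1.2 + fjc.b**2 * m**1.2) / 10.0
            mean_dist += w * d
    P /= Z
    pairs_weighted = [(s, w / Z) for (s, _), w in zip(items, weights)]
    return Z, P, mean_bp / Z, mean_dist / Z, pairs_weighted
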