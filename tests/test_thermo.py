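"""Partition function, sampler and enumeration oracle agreement."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy import stats

from rnaends import (NucleotideSequence, Partition, enumerate_structures,
                     mean_bp_probability, mean_pairing_probability,
                     partition_function, sample_structures,
                     stack_count_model, uniform_model)
from rnaends.thermo import DEFAULT_SAMPLE_SIZE

from conftest import boltzmann_summary, make_random_sequences


def count_structures_reference(seq, model):
    """Independent structure count: recursion on the FIRST position.

    Counts nested pairings (min hairpin 3, eligible letters) by
    conditioning on whether position i is unpaired or paired with k —
    a different interval decomposition than the enumerator, which
    conditions on the last position.
    """
    can, _, _ = model.pair_tables(seq.codes)

    memo = {}

    def count(i, j):
        if j - i < 4:
            return 1
        if (i, j) in memo:
            return memo[(i, j)]
        total = count(i + 1, j)  # i unpaired
        for k in range(i + 4, j + 1):
            if can[i, k]:
                total += count(i + 1, k - 1) * count(k + 1, j)
        memo[(i, j)] = total
        return total

    return count(0, len(seq) - 1)


class TestEnumeration:
    def test_homopolymer_has_single_empty_structure(self, uniform):
        items = enumerate_structures(NucleotideSequence("a", "AAAAAA"),
                                     uniform)
        assert len(items) == 1
        structure, energy = items[0]
        assert structure.n_pairs == 0 and energy == 0.0

    def test_gcgcgc_has_exactly_two_structures(self, uniform):
        items = enumerate_structures(NucleotideSequence("g", "GCGCGC"),
                                     uniform)
        brackets = sorted(s.to_dotbracket() for s, _ in items)
        assert brackets == ["(....)", "......"]

    @pytest.mark.parametrize("residues", ["GGGAAACCC", "GCAUGCAUGCAU",
                                          "GGGGAAAACCCCAA"])
    def test_count_matches_independent_recursion(self, residues, uniform):
        seq = NucleotideSequence("x", residues)
        assert len(enumerate_structures(seq, uniform)) == \
            count_structures_reference(seq, uniform)

    def test_enumeration_guard_refuses_long_sequences(self, uniform):
        seq = NucleotideSequence("long", "A" * 31)
        with pytest.raises(ValueError, match="guard"):
            enumerate_structures(seq, uniform)

    def test_empty_structure_always_present_with_zero_energy(self,
                                                             stacking):
        items = enumerate_structures(NucleotideSequence("x", "GGGAAACCC"),
                                     stacking)
        empty = [e for s, e in items if s.n_pairs == 0]
        assert empty == [0.0]


class TestPartitionFunction:
    def test_no_pairs_gives_unit_partition(self, uniform):
        pm = partition_function(NucleotideSequence("a", "AAAAAA"), uniform)
        assert pm.Z == pytest.approx(1.0)
        assert pm.P.max() == 0.0
        assert mean_bp_probability(pm) == 0.0

    def test_gcgcgc_uniform_half_probability(self, uniform):
        pm = partition_function(NucleotideSequence("g", "GCGCGC"), uniform)
        assert pm.Z == pytest.approx(2.0)
        assert pm.probability(1, 6) == pytest.approx(0.5)
        assert mean_bp_probability(pm) == pytest.approx(1 / 6)

    def test_oracle_equivalence_on_random_sequences(self, uniform,
                                                    stacking):
        fjc = None
        for seq in make_random_sequences(25, 5, 14, seed=101):
            for model in (uniform, stacking):
                Z, P, mean_bp, _, _ = boltzmann_summary(seq, model, fjc)
                part = Partition(seq, model)
                pm = part.pair_probabilities()
                assert pm.Z == pytest.approx(Z, rel=1e-9)
                assert np.abs(pm.P - P).max() < 1e-9
                assert mean_bp_probability(pm) == pytest.approx(
                    mean_bp, abs=1e-9)
                assert part.mean_bp_probability == pytest.approx(
                    mean_bp, abs=1e-9)

    def test_matrix_invariants(self, stacking):
        for seq in make_random_sequences(10, 8, 30, seed=7):
            pm = partition_function(seq, stacking)
            assert pm.Z >= 1.0
            assert pm.P.min() >= 0.0 and pm.P.max() <= 1.0 + 1e-12
            row_sums = pm.P.sum(axis=1)
            assert row_sums.max() <= 1.0 + 1e-9

    def test_mean_paths_agree_at_scale(self, stacking):
        seq = make_random_sequences(1, 150, 150, seed=3)[0]
        pm = partition_function(seq, stacking)
        assert mean_pairing_probability(seq, stacking) == pytest.approx(
            mean_bp_probability(pm), abs=1e-9)

    def test_disallowing_wobble_never_increases_z(self):
        with_w = stack_count_model(allow_wobble=True)
        without_w = stack_count_model(allow_wobble=False)
        for seq in make_random_sequences(10, 10, 40, seed=13):
            assert Partition(seq, without_w).log_z <= \
                Partition(seq, with_w).log_z + 1e-12

    def test_scaling_handles_transcript_lengths(self, stacking):
        seq = make_random_sequences(1, 400, 400, seed=5)[0]
        part = Partition(seq, stacking)
        assert math.isfinite(part.log_z) and part.log_z > 0
        assert 0.0 < part.mean_bp_probability < 1.0


class TestSampler:
    def test_homopolymer_samples_are_all_empty(self, uniform):
        sample = sample_structures(NucleotideSequence("a", "AAAAAA"),
                                   uniform, count=100, seed=1)
        assert all(s.n_pairs == 0 for s in sample.structures)

    def test_gcgcgc_frequency_within_binomial_interval(self, uniform):
        sample = sample_structures(NucleotideSequence("g", "GCGCGC"),
                                   uniform, count=1000, seed=2)
        paired = sum(s.n_pairs for s in sample.structures)
        lo, hi = stats.binom.interval(0.99, 1000, 0.5)
        assert lo <= paired <= hi

    def test_default_sample_size_is_one_thousand(self, uniform):
        import inspect
        from rnaends import ensemble_end_to_end
        assert DEFAULT_SAMPLE_SIZE == 1000
        for fn in (sample_structures, ensemble_end_to_end):
            assert inspect.signature(fn).parameters["count"].default == 1000

    def test_total_variation_against_exact_probabilities(self, uniform,
                                                         stacking):
        for seed, seq in enumerate(make_random_sequences(3, 9, 14, seed=23)):
            for model in (uniform, stacking):
                _, _, _, _, probs = boltzmann_summary(seq, model)
                exact = {s.to_dotbracket(): p for s, p in probs}
                sample = sample_structures(seq, model, count=10000,
                                           seed=seed)
                freq = Counter(s.to_dotbracket()
                               for s in sample.structures)
                tv = 0.5 * sum(abs(freq.get(k, 0) / 10000 - p)
                               for k, p in exact.items())
                assert tv < 0.05

    def test_determinism_and_seed_sensitivity(self, stacking):
        seq = NucleotideSequence("d", "GGGAAACCCGGGAAACCC")
        first = sample_structures(seq, stacking, count=60, seed=9)
        second = sample_structures(seq, stacking, count=60, seed=9)
        other = sample_structures(seq, stacking, count=60, seed=10)
        assert first.structures == second.structures
        assert first.structures != other.structures

    def test_invalid_count_rejected(self, stacking):
        seq = NucleotideSequence("d", "GGGAAACCC")
        with pytest.raises(ValueError):
            sample_structures(seq, stacking, count=0, seed=1)

    def test_samples_satisfy_structure_invariants(self, stacking):
        seq = make_random_sequences(1, 40, 40, seed=31)[0]
        sample = sample_structures(seq, stacking, count=200, seed=4)
        for structure in sample.structures:
            structure.validate_for(seq)  # raises on any violation
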