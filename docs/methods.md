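# Methods

## The quantity being modeled

Long RNAs do not behave like random coils: intramolecular base pairing
pulls the 5′ and 3′ termini of an mRNA or lncRNA to within a few
nanometers of each other, a distance regime measurable by FRET between
end-attached dyes. `rnaends` estimates the distribution of 5′–3′
end-to-end distances over the thermodynamic ensemble of nested secondary
structures, provides the genetic-algorithm machinery to *design*
sequences that escape this compaction (intrinsically unstructured,
optionally non-repetitive RNAs), and converts ensemble-FRET summaries
into distances for comparison.

## Ensemble model

A secondary structure is a pseudoknot-free partial pairing of positions
with canonical (A–U, G–C) or wobble (G–U) pairs and hairpin loops of at
least three nucleotides. Tertiary contacts and pseudoknots are outside
the model, so predicted distances for RNAs dominated by such contacts
(e.g. rRNA) will be underestimates of their structural complexity.

Energies are assigned by a pluggable, helix-decomposable
`EnergyModel`: each stacked pair couple contributes a constant
stabilizing term (default −2.0 kcal/mol, or −1.0 when either pair of the
couple is a G–U wobble), a lone pair contributes −0.5 kcal/mol, loops
contribute nothing, and the empty structure has energy exactly 0.
Temperature defaults to 310.15 K (RT in kcal/mol). Two built-ins:

* `uniform` — every admissible structure has energy 0, so the partition
  value counts structures. This is the model used against the
  enumeration oracle, because every test quantity has an exact
  combinatorial meaning.
* `stack-count` — the constant-stack model above; the default for
  ensemble predictions. It reproduces the qualitative physics that
  matters here (pairing propensity grows with stem length and G content;
  wobble pairs make G-containing sequences hard to keep unstructured)
  without the full nearest-neighbor parameter tables, which are
  deliberately out of scope. Distances computed under it land in the
  few-nanometer regime for natural-composition transcripts, but absolute
  values should not be read as calibrated thermodynamics.

### Partition function and pair probabilities

Inside recursion over segment sums `W` plus two helix arrays keyed by
context — `Vx` (pair seen from a loop, which may be isolated) and `Vp`
(pair stacked under its parent, never isolated) — so the stack/lone-pair
energies decompose exactly. The outside pass mirrors the same contexts
and accumulates enclosing-loop weights through an incremental array,
keeping the whole computation O(L³) time, O(L²) memory. The mean
base-pairing probability (mean over positions of the probability of
being paired, the design fitness) is also available without the outside
pass via a forward-mode derivative of the partition value with respect
to a per-pair multiplier; the two routes agree to 1e−9 and both are
tested against brute force.

All arrays carry a per-position scale factor `s` (so the scaled
partition value is `Z/s^L`); `s` is chosen by an adaptive loop that
renormalizes the scaled Z into a safe magnitude window, because
unscaled Z overflows float64 beyond roughly 300 nt. Reported is
`log Z`; `Z` itself is exposed where it is representable. Numerical
ties in the stochastic traceback (roundoff residue at the end of a
cumulative scan) fall back to the last positive option.

### Stochastic sampling

Structures are drawn by conditional-probability traceback of the inside
arrays, so each draw is an independent structure whose probability
equals its Boltzmann probability. The sampler is seeded and
reproducible: identical `(sequence, model, count, seed)` give
bit-identical samples. The default sample size is 1000 structures.
Sampled frequencies are tested by chi-square against exact enumeration
probabilities (α = 0.001, 10,000 draws) and by total-variation distance.

### Exhaustive enumeration oracle

`enumerate_structures` recursively enumerates every admissible structure
(conditioning on the last position of each interval) and scores each
with a standalone structure-level energy function. It refuses sequences
longer than 30 nt — counts grow exponentially — and exists to validate
the dynamic programming, the sampler and the Boltzmann-weighted distance
mean on sequences up to 14 nt, where everything is checked to 1e−9.
The test suite also carries a second, differently-decomposed counting
recursion (conditioning on the first position) as an independent check
of the enumerator itself.

## End-to-end distance

For each sampled structure the exterior loop — the loop containing both
termini — is scanned: `n` unpaired exterior nucleotides and `m` helices
branching off it. The two-scale freely jointed chain gives

    D = sqrt(a² · n^(6/5) + b² · m^(6/5)),   a = 6.2 Å, b = 15 Å,

with each exterior helix contributing exactly one rigid segment
regardless of its length (only its presence counts toward `m`). The 6/5
exponent and the segment scales come from a prior excluded-volume
parameterization of single-stranded RNA and are used verbatim.
Parameters are stored in Å, distances reported in nm. The fully
unpaired chain gives the random-coil reference `a·L^(3/5)`: 46 nm at
1327 nt, ≈5 nm at 30 nt. Note the random-coil value is *not* a strict
upper bound per structure — a lone exterior helix can nudge `D` slightly
past it — so ensemble means are only bounded by it up to sampling noise.

The ensemble mean is the arithmetic mean of per-structure distances
across the sample; a histogram (0.5-nm bins from zero to the random-coil
value, extended if a sample exceeds it) is attached to every
distribution. Poly(A) tails are assumed unpaired and are not folded;
an optional flag adds the tail's random-coil extension in quadrature.

## Sequence design (genetic algorithm)

A population (default 50) evolves by per-nucleotide mutation (default
0.01/nt, substituting a uniformly chosen different base) and single
cut-point crossover (rate 0.3), with truncation selection keeping the
best half as parents and elitism (default 5) guaranteeing the best
fitness is non-increasing. Only positions inside the configured region
mutate, but fitness is always the mean base-pairing probability of the
*full* sequence — pairing is global. In `min_bp_with_complexity` mode a
penalty `penalty_weight · max(0, complexity_floor − LC)` (defaults 1.0
and 0.35) keeps the evolved region non-repetitive. These GA
hyperparameters are conventional choices, all exposed in `GaConfig`.

Linguistic complexity is `LC = Π_{k=1..k_max} U_k` with
`U_k = distinct k-mers / min(4^k, L − k + 1)`, `k_max = 6` by default —
word sizes at which the vocabulary bound is informative for
100–2000-nt sequences. LC lies in (0, 1]; homopolymers and short
tandem repeats (e.g. (CA)₅₃, LC < 0.2) score low. The precise
complexity variant and GA schedule are this package's own documented
definitions; composition and complexity are reported for the mutable
region, fitness for the whole molecule.

Per-iteration trajectory records use a reduced 100-structure ensemble
for the distance (cost/smoothness trade-off); the final iteration uses
the full 1000. On a scaled run (150-nt random fixture, population 20,
300 iterations) the algorithm reproduces the expected phenomenology:
guanosines vanish, complexity collapses, mean pairing probability
reaches ~0 and the mean distance climbs from ~2.5 nm to the random-coil
value (12.5 nm), with complexity and distance strongly anti-correlated.

## Sequence utilities

Region shuffles preserve the mononucleotide multiset exactly (a uniform
permutation of the region letters); dinucleotide-preserving shuffles are
out of scope. Random sequences draw letters i.i.d. from a
`CompositionSpec` (GC fraction, A:(A+U) and G:(G+C) splits; splits
default to 0.5 each, since the natural-message splits they emulate are a
property of whichever transcript is being mimicked and are passed in by
the caller). The GC scan sweeps 0–100% GC in 5% steps (21 points),
generating `n_per_point` (default 100) sequences per point, running the
full ensemble pipeline on each and averaging the per-sequence means;
length defaults to 1327 nt but is a parameter so tests can scale down.

## FRET arithmetic

`efficiency_from_ratioA` implements
`E = (1/d⁺)(ε_A(635)/ε_D(540))(ratioA − ε_A(540)/ε_A(635))`; results
outside [0, 1] (noisy inputs) are returned with a warning, not clamped,
to keep the experimental reduction auditable. `E = 1/(1 + (R/R0)^6)`
with R0 = 56 Å (Cy3–Cy5) converts between efficiency and inter-dye
distance; the inverse is defined on 0 < E < 1 and round-trips to 1e−9.
Distances are Å-in/Å-out; nm appears only at reporting boundaries.

## Problem sizes and what the tests show

The test and acceptance suites run at desk scale by design: oracle
comparisons at L ≤ 14 (where enumeration is exact), sampler goodness of
fit at L ≤ 12 with 10,000 draws, the design GA at 150 nt with a
population of 20 over 300 iterations, and the GC scan at 120 nt with 10
sequences per point — sizes chosen so each property is still a sharp
test of the algorithm while whole suites complete in minutes.
Full-length (1327-nt) single-sequence ensembles run in seconds and are
exercised in examples; transcriptome-scale sweeps are supported by the
CLI but require external sequence sets and calibrated thermodynamic
parameters to be quantitatively meaningful.

Because fixtures are synthetic i.i.d. or shuffled sequences, passing
tests demonstrate correctness of the algorithms and the qualitative
sequence-structure phenomenology, not calibrated predictions for any
specific natural transcript: real UTRs have local composition biases
and evolved motifs the generators do not emulate, and the simplified
energy models trade quantitative accuracy for exactness of the oracle
chain.

## Known limitations

* No pseudoknots, tertiary contacts, dangles or coaxial stacking; no
  Turner parameter tables (the energy interface is pluggable so they
  can be added).
* The FJC treats every exterior helix as one rigid segment of fixed
  length b, ignoring helix length and flexibility.
* Ionic conditions are not modeled; temperature is a config field.
* GA runs are stochastic; all reported behaviors are for fixed seeds.
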