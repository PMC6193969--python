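"""Pluggable secondary-structure energy models.

The thermodynamic machinery in this package (partition function, sampling)
only requires that a structure's free energy decompose over helices:

* each *stack* — two base pairs (i, j) and (i+1, j-1) both present — carries
  a constant stabilizing energy, less favorable when either pair of the
  couple is a G-U wobble;
* an *isolated* pair (a helix of a single pair) carries its own small term;
* the empty structure has energy exactly 0; there are no loop terms.

Two built-ins are provided.  ``uniform`` assigns every admissible structure
energy 0, so the partition value simply counts structures — the model used
by the exhaustive-enumeration oracle tests.  ``stack-count`` is a coarse
stand-in for a nearest-neighbor model: -2.0 kcal/mol per Watson-Crick
stack, -1.0 per stack involving a wobble pair, -0.5 per lone pair.
Energies are in kcal/mol and the temperature is physiological by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sequence import NucleotideSequence
from .structure import MIN_HAIRPIN, WC_PAIRS, WOBBLE_PAIRS, SecondaryStructure

#: gas constant, kcal / (mol K)
R_KCAL = 1.987204258640832e-3


@dataclass(frozen=True)
class EnergyModel:
    """Helix-decomposable energy rule.

    Attributes
    ----------
    name:
        Label recorded in outputs.
    temperature:
        Kelvin; RT is computed in kcal/mol.
    wc_stack, wobble_stack:
        Energy of a stacked pair couple; the wobble value applies when either
        pair of the couple is G-U.
    isolated_pair:
        Energy of a lone (unstacked) pair.
    allow_wobble:
        Whether G-U pairs are admissible at all.
    """

    name: str
    temperature: float = 310.15
    wc_stack: float = -2.0
    wobble_stack: float = -1.0
    isolated_pair: float = -0.5
    allow_wobble: bool = True

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        for v in (self.wc_stack, self.wobble_stack, self.isolated_pair):
            if not math.isfinite(v):
                raise ValueError("all energies must be finite")

    @property
    def rt(self) -> float:
        """RT in kcal/mol."""
        return R_KCAL * self.temperature

    # -- tables consumed by the DP kernels ----------------------------
    def pair_tables(self, codes: np.ndarray):
        """Eligibility and Boltzmann-factor tables for a coded sequence.

        Returns ``(can, bst, biso)`` where ``can[i, j]`` marks admissible
        pairs (eligible letters, hairpin >= 3, i < j), ``bst[i, j]`` is the
        Boltzmann factor of the stack formed by (i, j) on (i+1, j-1), and
        ``biso`` the factor of an isolated pair.
        """
        L = codes.shape[0]
        allowed = WC_PAIRS | WOBBLE_PAIRS if self.allow_wobble else WC_PAIRS
        pairable = np.zeros((4, 4), dtype=bool)
        wobble = np.zeros((4, 4), dtype=bool)
        for a, b in allowed:
            pairable[a, b] = True
        for a, b in WOBBLE_PAIRS:
            wobble[a, b] = True
        can = pairable[codes[:, None], codes[None, :]]
        isgu = wobble[codes[:, None], codes[None, :]]
        ii, jj = np.indices((L, L))
        can &= jj - ii - 1 >= MIN_HAIRPIN
        # stack of (i,j) on (i+1,j-1): wobble rate if either pair is G-U
        stack_wobble = isgu.copy()
        stack_wobble[:-1, 1:] |= isgu[1:, :-1]
        e_stack = np.where(stack_wobble, self.wobble_stack, self.wc_stack)
        bst = np.exp(-e_stack / self.rt)
        biso = math.exp(-self.isolated_pair / self.rt)
        return can, bst, biso

    # -- whole-structure energy (used by the enumeration oracle) ------
    def structure_energy(self, seq: NucleotideSequence,
                         structure: SecondaryStructure) -> float:
        """Energy of a complete structure, in kcal/mol.

        Evaluated directly from the pair list (helix decomposition), with
        no reference to the dynamic-programming recursions, so it can serve
        as an independent check of them.
        """
        structure.validate_for(seq, allow_wobble=self.allow_wobble)
        codes = seq.codes
        pairset = set(structure.pairs)

        def is_gu(i: int, j: int) -> bool:
            return (int(codes[i - 1]), int(codes[j - 1])) in WOBBLE_PAIRS

        energy = 0.0
        for i, j in pairset:
            inner = (i + 1, j - 1) in pairset
            outer = (i - 1, j + 1) in pairset
            if inner:
                wob = is_gu(i, j) or is_gu(i + 1, j - 1)
                energy += self.wobble_stack if wob else self.wc_stack
            if not inner and not outer:
                energy += self.isolated_pair
        return energy


def uniform_model(temperature: float = 310.15,
                  allow_wobble: bool = True) -> EnergyModel:
    """Every admissible structure has energy 0 (Z counts structures)."""
    return EnergyModel(name="uniform", temperature=temperature,
                       wc_stack=0.0, wobble_stack=0.0, isolated_pair=0.0,
                       allow_wobble=allow_wobble)


def stack_count_model(temperature: float = 310.15,
                      allow_wobble: bool = True) -> EnergyModel:
    """Constant-energy stacking model (default for ensemble predictions)."""
    return EnergyModel(name="stack-count", temperature=temperature,
                       allow_wobble=allow_wobble)
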