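"""Ensemble-FRET arithmetic.

From spectrofluorometer summaries to inter-dye distances:

* ratioA — acceptor emission under donor-band excitation divided by
  acceptor emission under direct acceptor excitation — is converted to a
  FRET efficiency E by correcting for the donor-labeled fraction d+ and
  the dye extinction coefficients;
* E relates to the inter-dye distance R through the Foerster equation
  E = 1 / (1 + (R/R0)^6), with R0 = 56 A for the Cy3-Cy5 pair.

Distances here are in angstroms; conversion to nm happens only at
reporting boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

#: Foerster radius of the Cy3-Cy5 pair, angstroms
DEFAULT_R0 = 56.0


class EfficiencyRangeWarning(UserWarning):
    """Raised (as a warning) when noisy inputs give E outside [0, 1]."""


@dataclass(frozen=True)
class FretMeasurement:
    """Inputs of the ratioA efficiency estimate.

    Extinction coefficients are in 1/(M cm): ``eps_A_635`` acceptor at
    635 nm, ``eps_D_540`` donor at 540 nm, ``eps_A_540`` acceptor at
    540 nm.  ``d_plus`` is the fraction of molecules carrying the donor.
    """

    ratioA: float
    d_plus: float
    eps_A_635: float
    eps_D_540: float
    eps_A_540: float
    R0: float = DEFAULT_R0

    def __post_init__(self) -> None:
        if not (0.0 < self.d_plus <= 1.0):
            raise ValueError("d_plus must be in (0, 1]")
        for name in ("eps_A_635", "eps_D_540", "eps_A_540"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.R0 <= 0:
            raise ValueError("R0 must be positive")


def efficiency_from_ratioA(meas: FretMeasurement) -> float:
    """E = (1/d+) (eps_A(635)/eps_D(540)) (ratioA - eps_A(540)/eps_A(635)).

    Out-of-range results from noisy inputs are returned as-is with an
    :class:`EfficiencyRangeWarning` rather than clamped, preserving the
    auditability of the experimental reduction.
    """
    e = (1.0 / meas.d_plus) * (meas.eps_A_635 / meas.eps_D_540) * (
        meas.ratioA - meas.eps_A_540 / meas.eps_A_635)
    if not (0.0 <= e <= 1.0):
        warnings.warn(
            f"FRET efficiency {e:.4f} outside [0, 1]; check ratioA, d_plus "
            "and extinction coefficients", EfficiencyRangeWarning,
            stacklevel=2)
    return e


def efficiency_from_distance(R: float, R0: float = DEFAULT_R0) -> float:
    """E = 1 / (1 + (R/R0)^6) for an inter-dye distance R (angstroms)."""
    if R < 0:
        raise ValueError("distance R must be non-negative")
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    return 1.0 / (1.0 + (R / R0) ** 6)


def distance_from_efficiency(E: float, R0: float = DEFAULT_R0) -> float:
    """R = R0 ((1 - E)/E)^(1/6), angstroms; defined for 0 < E < 1."""
    if not (0.0 < E < 1.0):
        raise ValueError(
            "distance is undefined for E <= 0 (infinite separation) or "
            "E >= 1 (zero separation); got E = " + repr(E))
    if R0 <= 0:
        raise ValueError("R0 must be positive")
    return R0 * ((1.0 - E) / E) ** (1.0 / 6.0)
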