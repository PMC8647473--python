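"""Henderson-Hasselbalch speciation of weak carboxylic acids.

Only the undissociated (protonated) species is membrane-permeant and
solvent-extractable; its concentration, not the total carboxylate, drives
both product toxicity and liquid-liquid extraction.  The fraction of a
monoprotic acid in the undissociated form at a given pH is

    f_HA = 1 / (1 + 10**(pH - pKa))

which is 0.5 at pH == pKa and strictly decreasing in pH.
"""

from __future__ import annotations

import math

from .compounds import Compound, mM_to_g_per_L

__all__ = ["undissociated_fraction", "undissociated_conc", "undissociated_mM_as_g_per_L"]


def undissociated_fraction(pH: float, pKa: float) -> float:
    """Fraction of a monoprotic acid present as the undissociated species."""
    if not (math.isfinite(pH) and math.isfinite(pKa)):
        raise ValueError(f"pH and pKa must be finite, got pH={pH}, pKa={pKa}")
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def undissociated_conc(total: float, pH: float, compound: Compound) -> float:
    """Undissociated-acid concentration, in the same unit as ``total``.

    ``total`` is the summed concentration of dissociated + undissociated
    forms (g/L or mM -- the fraction is unit-agnostic).
    """
    if compound.pKa is None:
        raise ValueError(f"{compound.name} has no pKa; speciation undefined")
    if total < 0:
        raise ValueError(f"total concentration must be >= 0, got {total}")
    return total * undissociated_fraction(pH, compound.pKa)


def undissociated_mM_as_g_per_L(conc_mM: float, compound: Compound) -> float:
    """Express an undissociated-acid concentration given in mM as g/L.

    Convenience for the threshold arithmetic used when comparing toxicity
    limits (e.g. 26 mM undissociated n-caproic acid is ~3 g/L).
    """
    return mM_to_g_per_L(conc_mM, compound)
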