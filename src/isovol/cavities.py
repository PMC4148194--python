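"""Cavity fields and the volume algebra comparing two cavities.

A *cavity field* is the CSG intersection of a solid isopotential with a
binding-cavity solid: the electrostatically significant region a ligand can
actually reach.  Two (pre-aligned) cavities are compared inside
``I = C_A ∩ C_B`` — the region solvent-accessible in both — so that the
comparison is purely electrostatic and not influenced by steric differences:
``e_A = E_A ∩ I`` and ``e_B = E_B ∩ I``, their intersection is conserved
electrostatic character, and the CSG differences are regions that one cavity
charges and the other does not.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lattice import ThresholdSpec
from .solids import SolidRegion, complement, intersection

__all__ = ["CavityComparison", "cavity_field", "compare_cavities"]


def cavity_field(iso: SolidRegion, cavity: SolidRegion) -> SolidRegion:
    """CSG intersection of a solid isopotential with a cavity solid."""
    iso.lattice.require_congruent(cavity.lattice, "cavity field")
    return intersection(iso, cavity)


@dataclass
class CavityComparison:
    """Volume algebra of two cavity fields clipped to the shared region I."""

    I: SolidRegion
    eA: SolidRegion
    eB: SolidRegion
    v_conserved: float
    v_A_minus_B: float
    v_B_minus_A: float
    k: ThresholdSpec


def compare_cavities(
    EA: SolidRegion,
    EB: SolidRegion,
    CA: SolidRegion,
    CB: SolidRegion,
    k: ThresholdSpec,
) -> CavityComparison:
    """Compare two cavities' isopotential solids inside their shared region.

    ``EA``/``EB`` are solid isopotentials of the two (aligned) structures at
    the same threshold; ``CA``/``CB`` their cavity solids.  All four must be
    on congruent lattices.
    """
    for other in (EB, CA, CB):
        EA.lattice.require_congruent(other.lattice, "cavity comparison")
    I = intersection(CA, CB)
    if I.is_empty():
        raise ValueError(
            "cavities do not overlap after alignment: I = C_A ∩ C_B is empty"
        )
    eA = intersection(EA, I)
    eB = intersection(EB, I)
    # clipping guarantees eA, eB ⊆ I
    assert not (eA.occupancy & ~I.occupancy).any()
    assert not (eB.occupancy & ~I.occupancy).any()
    # because eA, eB ⊆ I, the differences flatten to pure intersections
    # (eA - eB = EA ∩ I ∩ ¬EB), which keeps operand crossings exact
    return CavityComparison(
        I=I,
        eA=eA,
        eB=eB,
        v_conserved=intersection(eA, eB).volume(),
        v_A_minus_B=intersection(eA, complement(EB)).volume(),
        v_B_minus_A=intersection(eB, complement(EA)).volume(),
        k=k,
    )
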