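"""Interface fields: solid measures of electrostatic complementarity.

For two proteins A and B in complex and a threshold k > 0 (kT/e), the
interface field at +k is the region inside the interface where A's *lone*
field (computed from A's charges only, at complex coordinates) is >= +k
while B's lone field is <= -k; the field at -k swaps the signs.  The summed
volume EC = V(i_pos) + V(i_neg) quantifies the complex's total electrostatic
complementarity on both sides of the potential spectrum, and

    ΔEC = EC_variant - EC_reference

compares two complexes: significantly negative ΔEC means complementarity is
diminished in the variant.

Under the fd_lpb model the partner's atoms stay in the dielectric mask even
though its charges are excluded (bound geometry, single-side charges), so
electrostatic focusing by the partner's bulk is retained; this is
configurable via ``partner_in_dielectric``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .electrostatics import ChargedStructure, ElectrostaticModel, compute_field
from .lattice import Lattice
from .regions import RegionParams, interface_lattice, interface_region
from .solids import SolidRegion

logger = logging.getLogger(__name__)

__all__ = [
    "InterfaceFieldSet",
    "interface_field",
    "make_field_set",
    "delta_EC",
    "INTERFACE_K_SWEEP",
]

#: Default threshold sweep for interface calibration (kT/e).
INTERFACE_K_SWEEP = (1.0, 3.0, 5.0, 7.0, 9.0)


def interface_field_from_potentials(
    phi_a: np.ndarray,
    phi_b: np.ndarray,
    region: SolidRegion,
    k: float,
) -> SolidRegion:
    """Interface field from precomputed lone potentials on region's lattice."""
    if k == 0:
        raise ValueError("k must be nonzero")
    if k > 0:
        sa = phi_a - k      # A at or above +k
        sb = (-k) - phi_b   # B at or below -k
    else:
        sa = k - phi_a      # A at or below k (< 0)
        sb = phi_b - (-k)   # B at or above -k (> 0)
    return SolidRegion(region.lattice, np.minimum(np.minimum(sa, sb), region.signed))


def interface_field(
    a: ChargedStructure,
    b: ChargedStructure,
    region: SolidRegion,
    k: float,
    model: ElectrostaticModel,
    partner_in_dielectric: bool = True,
) -> SolidRegion:
    """Region where A's lone field passes +k and B's lone field passes -k
    (signs swapped for k < 0), clipped to the interface region."""
    if k == 0:
        raise ValueError("k must be nonzero")
    if region.is_empty():
        raise ValueError("interface region is empty")
    phi_a = _lone_field(a, b, region.lattice, model, partner_in_dielectric)
    phi_b = _lone_field(b, a, region.lattice, model, partner_in_dielectric)
    return interface_field_from_potentials(phi_a, phi_b, region, k)


def _lone_field(
    s: ChargedStructure,
    partner: ChargedStructure,
    lat: Lattice,
    model: ElectrostaticModel,
    partner_in_dielectric: bool,
) -> np.ndarray:
    """Potential of one protein alone, at complex coordinates.

    The partner's charges are never sources; under fd_lpb its atoms may stay
    in the dielectric mask (as uncharged solvent-displacing bulk).
    """
    if model.model == "fd_lpb" and partner_in_dielectric:
        merged = ChargedStructure(
            s.atoms + [  # partner atoms, charges off
                a for a in partner.with_charges(
                    np.zeros(partner.n_atoms)
                ).atoms
            ]
        )
        return compute_field(merged, lat, model).values
    return compute_field(s, lat, model).values


@dataclass
class InterfaceFieldSet:
    """The two interface fields of one complex at ±k, and their summed volume."""

    region: SolidRegion
    i_pos: SolidRegion
    i_neg: SolidRegion
    k: float
    EC: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("field sets are indexed by k > 0")


def make_field_set(
    a: ChargedStructure,
    b: ChargedStructure,
    k: float,
    model: ElectrostaticModel,
    params: RegionParams | None = None,
    lattice: Lattice | None = None,
    region: SolidRegion | None = None,
) -> InterfaceFieldSet:
    """Interface fields of complex (A, B) at +k and -k, and EC their summed
    volume.  The interface region (and its lattice) are built from the 5 Å
    rules unless supplied."""
    if k <= 0:
        raise ValueError("k must be > 0; the -k field is built automatically")
    params = params or RegionParams()
    if region is None:
        if lattice is None:
            lattice = interface_lattice(a, b, params, spacing=0.5)
        region = interface_region(a, b, lattice, params)
    if region.is_empty():
        logger.warning("empty interface region: EC = 0")
        empty = SolidRegion.empty(region.lattice)
        return InterfaceFieldSet(region=region, i_pos=empty, i_neg=empty,
                                 k=k, EC=0.0)
    i_pos = interface_field(a, b, region, +k, model)
    i_neg = interface_field(a, b, region, -k, model)
    return InterfaceFieldSet(
        region=region, i_pos=i_pos, i_neg=i_neg, k=k,
        EC=i_pos.volume() + i_neg.volume(),
    )


def delta_EC(ref: InterfaceFieldSet, variant: InterfaceFieldSet) -> float:
    """ΔEC = variant.EC - ref.EC (ų); negative means the variant complex is
    less electrostatically complementary than the reference."""
    if ref.k != variant.k:
        raise ValueError(
            f"ΔEC requires matching thresholds, got {ref.k} vs {variant.k}"
        )
    return variant.EC - ref.EC
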