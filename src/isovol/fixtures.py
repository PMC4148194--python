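"""Deterministic synthetic charge systems with known ground truth.

Real validation of this kind of method uses protein families whose
specificity is understood residue-by-residue (serine/cysteine protease
pockets, charged two-body complexes); those structures, their fitted
charges and their aligned cavities cannot ship with a test suite.  These
generators build the smallest point-charge systems that exercise the same
inference paths with an unambiguous planted answer:

``planted_cavity_pair``
    Two structurally identical pseudo-proteins around a shared spherical
    cavity; the *test* copy carries one extra buried -1 e residue at the
    cavity base (the analogue of an acidic specificity residue at the bottom
    of a pocket).  Ground truth: nullifying that residue minimises the
    cavity-field difference v_r.

``opposing_complex``
    Two pseudo-proteins facing each other across a 6-10 Å gap, one +1 e
    residue opposing one -1 e residue (the analogue of a charged hot-spot
    pair), each with a neutral side-chain tip reaching into the interface so
    the 5 Å contact rule fires.  Ground truth: an interface scan labels
    exactly the charged residue as contributing complementarity.

Everything is reproducible from (scenario, seed) alone.  Decoy residues are
neutral and placed >= 15 Å from the cavity/interface so the planted signal
is unambiguous at the default thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .electrostatics import AtomRecord, ChargedStructure, ResidueID
from .lattice import Lattice
from .regions import sphere_union_solid
from .solids import SolidRegion

__all__ = [
    "FixtureSpec",
    "toy_structure",
    "planted_cavity_pair",
    "opposing_complex",
    "cavity_pair_lattice",
]

#: Shared cavity radius (Å) of the planted-cavity scenario.
CAVITY_RADIUS = 4.0
#: Planted charge position: buried just below the cavity base.
PLANTED_DEPTH = 5.2
#: Decoys live at least this far (Å) from the cavity centre / interface.
DECOY_CLEARANCE = 15.0


@dataclass(frozen=True)
class FixtureSpec:
    scenario: str
    seed: int
    params: dict = field(default_factory=dict)


def _atoms(
    entries: list[tuple[str, str, str, int, tuple[float, float, float], float, float]]
) -> ChargedStructure:
    """Build a structure from (name, resname, chain, resnum, pos, radius, q)."""
    records = [
        AtomRecord(
            serial=i + 1, name=name, residue_name=resname, chain=chain,
            residue_number=resnum, insertion_code="", position=pos,
            radius=radius, charge=q,
        )
        for i, (name, resname, chain, resnum, pos, radius, q) in enumerate(entries)
    ]
    return ChargedStructure(records)


def _warn_overlaps(s: ChargedStructure, min_separation: float = 0.5) -> None:
    """Warn about near-coincident atoms (bonded-distance overlap is normal)."""
    if s.n_atoms < 2:
        return
    from scipy.spatial import cKDTree

    tree = cKDTree(s.positions)
    for i, j in sorted(tree.query_pairs(min_separation)):
        d = np.linalg.norm(s.positions[i] - s.positions[j])
        warnings.warn(
            f"atoms {i + 1} and {j + 1} overlap beyond tolerance "
            f"(separation {d:.2f} Å)",
            stacklevel=3,
        )


def toy_structure(spec: FixtureSpec) -> ChargedStructure:
    """Small pseudo-protein described by a :class:`FixtureSpec`.

    Scenarios: ``"single_atom"`` (params: charge, radius, position) and
    ``"blob"`` (params: n_residues, extent, charge_fraction) — seeded random
    1-3 atom residues in a cube.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    if spec.scenario == "single_atom":
        s = _atoms([(
            "X", "UNK", "A", 1,
            tuple(p.get("position", (0.0, 0.0, 0.0))),
            float(p.get("radius", 1.5)), float(p.get("charge", 1.0)),
        )])
    elif spec.scenario == "blob":
        n = int(p.get("n_residues", 20))
        extent = float(p.get("extent", 15.0))
        charge_fraction = float(p.get("charge_fraction", 0.3))
        entries = []
        for res in range(1, n + 1):
            center = rng.uniform(-extent, extent, size=3)
            n_at = int(rng.integers(1, 4))
            q_res = (
                float(rng.choice([-1.0, 1.0]))
                if rng.random() < charge_fraction else 0.0
            )
            for a in range(n_at):
                pos = center + rng.normal(scale=0.8, size=3)
                entries.append((
                    f"X{a + 1}", "UNK", "A", res, tuple(pos),
                    float(rng.uniform(1.2, 1.9)),
                    q_res if a == 0 else 0.0,
                ))
        s = _atoms(entries)
    else:
        raise ValueError(f"unknown fixture scenario {spec.scenario!r}")
    _warn_overlaps(s)
    return s


def cavity_pair_lattice(spacing: float = 0.5) -> Lattice:
    """Working lattice for the planted-cavity scenario: a box comfortably
    around the shared 4 Å cavity."""
    half = CAVITY_RADIUS + 3.5
    return Lattice.from_bounds((-half,) * 3, (half,) * 3, spacing)


def _ring(radius: float, n: int, z: float) -> list[np.ndarray]:
    return [
        np.array([radius * np.cos(t), radius * np.sin(t), z])
        for t in np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    ]


def planted_cavity_pair(
    seed: int,
    n_decoys: int = 11,
    spacing: float = 0.5,
) -> tuple[ChargedStructure, ChargedStructure, SolidRegion, SolidRegion, ResidueID]:
    """Test/reference pseudo-proteins around a shared spherical cavity.

    Returns ``(test, ref, C_test, C_ref, planted_rid)``.  The reference is
    the test structure without the planted -1 e residue (everything else is
    identical and neutral, so the reference cavity field is empty and the
    baseline difference v0 is exactly the test cavity field's volume).
    """
    rng = np.random.default_rng(seed)
    entries = []
    # neutral scaffold ring around the cavity mouth
    for i, pos in enumerate(_ring(6.5, 8, 0.0), start=1):
        entries.append(("C1", "SCF", "A", i, tuple(pos), 1.8, 0.0))
    # neutral far decoys
    for i in range(n_decoys):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        dist = rng.uniform(DECOY_CLEARANCE + 1.0, DECOY_CLEARANCE + 7.0)
        entries.append((
            "C1", "DCY", "A", 101 + i, tuple(dist * direction), 1.7, 0.0,
        ))
    ref = _atoms(entries)
    planted_rid: ResidueID = ("A", 50, "")
    test = _atoms(entries + [
        ("OD1", "PLT", "A", 50, (0.0, 0.0, -PLANTED_DEPTH), 1.5, -1.0),
    ])
    lat = cavity_pair_lattice(spacing)
    cavity = sphere_union_solid(
        np.array([[0.0, 0.0, 0.0]]), np.array([CAVITY_RADIUS]), lat
    )
    c_ref = SolidRegion(lat, cavity.signed.copy())
    return test, ref, cavity, c_ref, planted_rid


def opposing_complex(
    seed: int,
    n_decoys: int = 11,
    partner_charge: float = -1.0,
) -> tuple[ChargedStructure, ChargedStructure]:
    """Two pseudo-proteins with opposing charges across a 6-10 Å gap.

    Side A carries one +1 e residue facing side B's ``partner_charge``
    residue; both charged residues extend a neutral tip atom to ~1.5 Å from
    the midplane so they fall inside the 5 Å interface rule.  All other
    residues are neutral decoys >= 15 Å away.  With the default -1 e partner
    the ground truth is that an interface scan on side A labels exactly the
    +1 e residue ``contributes_complementarity``.
    """
    rng = np.random.default_rng(seed)
    gap = float(rng.uniform(6.0, 10.0))

    def side(chain: str, sign: float, charge: float) -> ChargedStructure:
        entries = [
            ("Q1", "CHG", chain, 1, (0.0, 0.0, sign * gap / 2.0), 1.8, charge),
            ("T1", "CHG", chain, 1, (0.0, 0.0, sign * 1.5), 1.2, 0.0),
        ]
        for i in range(n_decoys):
            x, y = rng.uniform(-6.0, 6.0, size=2)
            z = sign * (gap / 2.0 + rng.uniform(DECOY_CLEARANCE, DECOY_CLEARANCE + 5.0))
            entries.append(("C1", "DCY", chain, 10 + i, (x, y, z), 1.7, 0.0))
        return _atoms(entries)

    a = side("A", +1.0, +1.0)
    b = side("B", -1.0, partner_charge)
    return a, b
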